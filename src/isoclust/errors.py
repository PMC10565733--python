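"""Exception hierarchy shared across the package."""


class IsoclustError(Exception):
    """Base class for package-specific failures."""


class ParseError(IsoclustError):
    """A reflection/cell table row could not be parsed (message names the line)."""


class HeaderError(IsoclustError):
    """A required header item (e.g. unit-cell constants) is missing or malformed."""


class FitError(IsoclustError):
    """A CC-distribution sample set is empty after filtering."""


class ConfigError(IsoclustError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(IsoclustError):
    """Input data cannot support the requested computation (CLI exit code 3)."""
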