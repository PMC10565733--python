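"""Pairwise intensity correlation and the d_CC distance matrix.

Isomorphism between two chunks is measured by the Pearson correlation
coefficient (CC) of their common-reflection intensities, computed on the
intersection of canonical (h, k, l) keys after an optional high-resolution
cutoff.  Three distance transforms are offered; the default,
d_CC = (1 - CC²)^1/2, maps CC ∈ [-1, 1] onto [0, 1] and is the transform used
for all downstream clustering in this package.

Pairs sharing fewer than ``min_common`` reflections carry no usable CC.  When
assembling a full matrix, chunks are greedily removed (most invalid pairs
first, ties broken by lexicographically smallest chunk_id) until every
retained pair is valid; removals are recorded in the matrix's exclusion list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError
from .reflections import ChunkCollection, ReflectionChunk, _encode_hkl
from .symmetry import POINT_GROUPS, map_to_asu_array

__all__ = [
    "CCEntry",
    "DistanceMatrix",
    "pearson_cc",
    "cc_to_distance",
    "build_distance_matrix",
    "METRICS",
]

METRICS = ("one_minus_cc", "sqrt_one_minus_cc", "sqrt_one_minus_cc2")
DEFAULT_METRIC = "sqrt_one_minus_cc2"


@dataclass(frozen=True)
class CCEntry:
    """Correlation of one chunk pair: cc is meaningful only when valid."""

    i: int
    j: int
    cc: float
    n_common: int
    valid: bool
    reason: str | None = None


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over retained chunks.

    ``excluded`` records chunks dropped before/while building the matrix as
    (chunk_id, reason) pairs.
    """

    labels: list[str]
    values: np.ndarray
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("values must be square and match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix entries must be finite")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Condensed upper-triangle vector (scipy ordering)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_tsv(self, path, excluded_path=None) -> None:
        """Square TSV with id header row/column; exclusions as a sidecar TSV."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("chunk_id\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")
        if excluded_path is not None:
            with open(excluded_path, "w", encoding="utf-8") as fh:
                fh.write("chunk_id\treason\n")
                for cid, reason in self.excluded:
                    fh.write(f"{cid}\t{reason}\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        labels = lines[0].split("\t")[1:]
        values = np.array(
            [[float(x) for x in ln.split("\t")[1:]] for ln in lines[1 : len(labels) + 1]]
        )
        return cls(labels=labels, values=values)


def cc_to_distance(cc, metric: str = DEFAULT_METRIC):
    """Transform correlation(s) into a clustering distance.

    one_minus_cc: 1 - CC (range [0, 2]); sqrt_one_minus_cc: (1 - CC)^1/2;
    sqrt_one_minus_cc2: (1 - CC²)^1/2 (range [0, 1], the d_CC default).
    """
    cc_arr = np.asarray(cc, dtype=float)
    if np.any(np.abs(cc_arr) > 1.0):
        raise ValueError("correlation coefficients must lie in [-1, 1]")
    if metric == "one_minus_cc":
        out = 1.0 - cc_arr
    elif metric == "sqrt_one_minus_cc":
        out = np.sqrt(1.0 - cc_arr)
    elif metric == "sqrt_one_minus_cc2":
        out = np.sqrt(np.maximum(0.0, 1.0 - cc_arr**2))
    else:
        raise ValueError(f"unknown metric {metric!r}; choose one of {METRICS}")
    return float(out) if out.ndim == 0 else out


def _filtered_keys(chunk: ReflectionChunk, d_min, ops) -> tuple[np.ndarray, np.ndarray]:
    """Canonical int64 keys and intensities after the resolution cutoff."""
    hkl = map_to_asu_array(chunk.hkl, ops)
    intens = chunk.intensity
    if d_min is not None:
        keep = chunk.d_spacings() >= d_min
        hkl, intens = hkl[keep], intens[keep]
    return _encode_hkl(hkl), intens


def pearson_cc(
    x: ReflectionChunk,
    y: ReflectionChunk,
    d_min: float | None = None,
    min_common: int = 3,
    ops=POINT_GROUPS["1"],
    i: int = 0,
    j: int = 1,
) -> CCEntry:
    """Pearson CC of two chunks over their common reflections.

    Each chunk is filtered with its own cell (d >= d_min); the pair uses the
    intersection of the filtered canonical index sets.  Entries with fewer
    than min_common shared reflections, or a constant intensity vector, are
    flagged invalid.
    """
    if min_common < 2:
        raise ValueError("min_common must be >= 2")
    kx, ix = _filtered_keys(x, d_min, ops)
    ky, iy = _filtered_keys(y, d_min, ops)
    common, ax, ay = np.intersect1d(kx, ky, assume_unique=True, return_indices=True)
    n = len(common)
    if n < min_common:
        return CCEntry(i, j, np.nan, n, False, "insufficient_common")
    vx, vy = ix[ax], iy[ay]
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        return CCEntry(i, j, np.nan, n, False, "degenerate")
    cc = float(np.corrcoef(vx, vy)[0, 1])
    return CCEntry(i, j, cc, n, True)


def _pairwise_cc_matrix(
    chunks, d_min, ops
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs CC and common-reflection counts, vectorised.

    Chunks are laid out on the union of their canonical keys; pairwise sums
    over joint observation masks reduce to three matrix products, so the cost
    is O(n_chunks² · n_union) in fast BLAS rather than a Python pair loop.
    """
    keys = []
    vals = []
    for c in chunks:
        k, v = _filtered_keys(c, d_min, ops)
        keys.append(k)
        vals.append(v)
    union = np.unique(np.concatenate(keys))
    n, u = len(chunks), len(union)
    W = np.zeros((n, u))
    A = np.zeros((n, u))
    for row, (k, v) in enumerate(zip(keys, vals)):
        pos = np.searchsorted(union, k)
        W[row, pos] = 1.0
        A[row, pos] = v
    N = W @ W.T
    Sx = A @ W.T            # Σ x_i over the joint mask of (i, j)
    Sxy = A @ A.T
    Sxx = (A * A) @ W.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = N * Sxy - Sx * Sx.T
        varx = N * Sxx - Sx**2
        cc = cov / np.sqrt(varx * varx.T)
    return cc, N.astype(np.int64)


def build_distance_matrix(
    chunks: ChunkCollection,
    d_min: float | None = None,
    min_common: int = 3,
    metric: str = DEFAULT_METRIC,
    ops=POINT_GROUPS["1"],
) -> DistanceMatrix:
    """Assemble the complete d_CC matrix over mutually comparable chunks.

    While any pair is invalid (too few common reflections, or a degenerate
    intensity vector), the chunk participating in the most invalid pairs is
    removed (ties: lexicographically smallest chunk_id) and recorded in
    ``excluded``.  Fewer than 3 survivors is a hard error.
    """
    ids = list(chunks.chunk_ids) if isinstance(chunks, ChunkCollection) else [
        c.chunk_id for c in chunks
    ]
    chunk_list = list(chunks)
    if len(chunk_list) < 3:
        raise DataError("need at least 3 chunks to build a distance matrix")

    cc, ncom = _pairwise_cc_matrix(chunk_list, d_min, ops)
    invalid = (ncom < min_common) | ~np.isfinite(cc)
    np.fill_diagonal(invalid, False)

    active = list(range(len(chunk_list)))
    excluded: list[tuple[str, str]] = []
    while True:
        sub = invalid[np.ix_(active, active)]
        counts = sub.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = counts.max()
        # ties → lexicographically smallest chunk_id
        cand = [active[t] for t in np.flatnonzero(counts == worst)]
        drop = min(cand, key=lambda t: ids[t])
        excluded.append((ids[drop], f"{int(invalid[drop, :].sum())} invalid pairs"))
        active.remove(drop)
        if len(active) < 3:
            raise DataError("insufficient mutually comparable chunks (fewer than 3 survive)")

    cc_sub = np.clip(cc[np.ix_(active, active)], -1.0, 1.0)
    dist = cc_to_distance(cc_sub, metric)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(
        labels=[ids[t] for t in active],
        values=(dist + dist.T) / 2.0,
        excluded=excluded,
    )
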