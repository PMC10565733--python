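"""Unit-cell-based clustering: Tukey pre-filtering, LCV, cell distances.

Before intensity-based clustering, chunks whose unit-cell constants are
outliers are removed with Tukey's interquartile-range rule.  Cells are
compared through their three face-diagonal lengths (the longer parallelogram
diagonal of each face); the *linear cell variation* (LCV) is the maximum
pairwise percentage change among those diagonals, and the cell distance used
for unit-cell HCA is the Euclidean distance between face-diagonal triples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cell import UnitCell
from .correlation import DistanceMatrix
from .errors import DataError, ParseError

__all__ = [
    "CellRecord",
    "LCVReport",
    "tukey_filter",
    "face_diagonals",
    "lcv",
    "cell_distance_matrix",
    "read_cell_table",
]


@dataclass(frozen=True)
class CellRecord:
    chunk_id: str
    cell: UnitCell


@dataclass(frozen=True)
class LCVReport:
    """Largest pairwise face-diagonal variation, as a percentage."""

    max_lcv_percent: float
    argmax_pair: tuple[str, str]

    def to_dict(self) -> dict:
        return {
            "max_lcv_percent": self.max_lcv_percent,
            "argmax_pair": list(self.argmax_pair),
        }


def tukey_filter(
    cells: list[CellRecord], k: float = 1.5
) -> tuple[list[CellRecord], list[CellRecord]]:
    """Reject cells with any parameter outside [Q1 - k·IQR, Q3 + k·IQR].

    Each of the six cell constants is screened independently.  With fewer
    than 4 records quartiles are meaningless, so everything passes with a
    warning.
    """
    if len(cells) < 4:
        warnings.warn("fewer than 4 cells: Tukey filter passed through", stacklevel=2)
        return list(cells), []
    params = np.array([rec.cell.parameters for rec in cells])  # (n, 6)
    q1, q3 = np.percentile(params, [25, 75], axis=0)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    ok = np.all((params >= lo) & (params <= hi), axis=1)
    retained = [rec for rec, keep in zip(cells, ok) if keep]
    rejected = [rec for rec, keep in zip(cells, ok) if not keep]
    return retained, rejected


def face_diagonals(cell: UnitCell) -> tuple[float, float, float]:
    """Longer parallelogram diagonal of each cell face: (d_ab, d_bc, d_ca).

    d_ab = max over sign of sqrt(a² + b² ± 2ab·cos γ), and cyclically for the
    other faces.
    """

    def longer(p: float, q: float, angle_deg: float) -> float:
        cross = 2.0 * p * q * abs(np.cos(np.radians(angle_deg)))
        return float(np.sqrt(p * p + q * q + cross))

    return (
        longer(cell.a, cell.b, cell.gamma),
        longer(cell.b, cell.c, cell.alpha),
        longer(cell.c, cell.a, cell.beta),
    )


def lcv(cells: list[CellRecord]) -> LCVReport:
    """Largest linear cell variation over all pairs and all three diagonals.

    For each pair and face diagonal: 100·|d_i - d_j| / min(d_i, d_j); the LCV
    is the maximum.  Zero iff all face-diagonal triples coincide.
    """
    if len(cells) < 2:
        raise DataError("LCV needs at least 2 cells")
    diags = np.array([face_diagonals(rec.cell) for rec in cells])  # (n, 3)
    best = -1.0
    best_pair = (cells[0].chunk_id, cells[1].chunk_id)
    for i in range(len(cells) - 1):
        di = diags[i]
        dj = diags[i + 1 :]
        rel = 100.0 * np.abs(di - dj) / np.minimum(di, dj)
        m = rel.max(axis=1)
        j_rel = int(np.argmax(m))
        if m[j_rel] > best:
            best = float(m[j_rel])
            best_pair = (cells[i].chunk_id, cells[i + 1 + j_rel].chunk_id)
    return LCVReport(max_lcv_percent=best, argmax_pair=best_pair)


def cell_distance_matrix(cells: list[CellRecord]) -> DistanceMatrix:
    """Euclidean distance between face-diagonal triples (Å), for cell HCA."""
    if len(cells) < 3:
        raise DataError("need at least 3 cells for a distance matrix")
    diags = np.array([face_diagonals(rec.cell) for rec in cells])
    diff = diags[:, None, :] - diags[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    return DistanceMatrix(labels=[rec.chunk_id for rec in cells], values=values)


def read_cell_table(path) -> list[CellRecord]:
    """Read a TSV cell table: chunk_id a b c alpha beta gamma."""
    records: list[CellRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if fields[0] == "chunk_id":
                continue
            if len(fields) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 fields, got {len(fields)}")
            try:
                records.append(CellRecord(fields[0], UnitCell(*map(float, fields[1:]))))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return records
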