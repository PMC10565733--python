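"""Reflection chunks: reading, validation, and angular partitioning.

A *chunk* is a contiguous angular slice (typically 30°) of a continuous
helical rotation data set, processed as an independent partial data set.  Each
chunk holds unique (h, k, l) → (intensity, sigma) records; splitting a
frame-tagged observation stream into chunks merges symmetry-equivalent
observations within a chunk by inverse-variance weighting.

Two plain-text dialects are supported: a simple TSV table
(``h k l intensity sigma [frame]``, '#' comments) and a minimal XDS-ASCII
style format ('!'-prefixed headers carrying the unit-cell constants and
space-group number).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cell import UnitCell
from .errors import HeaderError, ParseError
from .symmetry import POINT_GROUPS, map_to_asu_array

__all__ = [
    "ReflectionChunk",
    "ChunkCollection",
    "read_chunk_table",
    "write_chunk_table",
    "write_xds_ascii",
    "split_into_chunks",
]

_REQUIRED_COLUMNS = ("h", "k", "l", "intensity", "sigma")


@dataclass
class ReflectionChunk:
    """One angular chunk's unique reflections plus identity and geometry.

    ``records`` is a DataFrame with columns h, k, l (int), intensity, sigma
    (float) and optionally frame (int ≥ 1); (h, k, l) rows are unique.
    """

    chunk_id: str
    crystal_id: str
    records: pd.DataFrame
    cell: UnitCell
    rotation_start_deg: float = 0.0
    rotation_end_deg: float = 30.0
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.rotation_end_deg > self.rotation_start_deg:
            raise ValueError("rotation_end_deg must exceed rotation_start_deg")
        df = self.records
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        if (df["sigma"] < 0).any():
            raise ValueError("sigma must be non-negative")
        hkl = df[["h", "k", "l"]].to_numpy()
        if np.any(~hkl.any(axis=1)):
            raise ValueError("(0,0,0) is not a valid reflection index")
        if len(df) != len(np.unique(_encode_hkl(hkl))):
            raise ValueError(f"duplicate (h,k,l) keys in chunk {self.chunk_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def hkl(self) -> np.ndarray:
        return self.records[["h", "k", "l"]].to_numpy(dtype=np.int64)

    @property
    def intensity(self) -> np.ndarray:
        return self.records["intensity"].to_numpy(dtype=float)

    @property
    def sigma(self) -> np.ndarray:
        return self.records["sigma"].to_numpy(dtype=float)

    def d_spacings(self) -> np.ndarray:
        """Resolution of every record, Å."""
        h, k, l = self.hkl.T
        return self.cell.d_spacing(h, k, l)


@dataclass
class ChunkCollection:
    """Ordered chunks with unique ids plus provenance of how they were made."""

    chunks: list[ReflectionChunk]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.chunk_id for c in self.chunks]
        if len(ids) != len(set(ids)):
            raise ValueError("chunk_ids must be unique within a collection")

    def __len__(self) -> int:
        return len(self.chunks)

    def __iter__(self):
        return iter(self.chunks)

    def __getitem__(self, i):
        return self.chunks[i]

    @property
    def chunk_ids(self) -> list[str]:
        return [c.chunk_id for c in self.chunks]

    @property
    def labels(self) -> list[str | None]:
        return [c.label for c in self.chunks]


def _encode_hkl(hkl: np.ndarray) -> np.ndarray:
    """Pack index triples into single int64 keys (|index| < 2**20)."""
    hkl = np.asarray(hkl, dtype=np.int64)
    off = 1 << 20
    return ((hkl[:, 0] + off) << 42) | ((hkl[:, 1] + off) << 21) | (hkl[:, 2] + off)


def merge_equivalents(df: pd.DataFrame, ops=POINT_GROUPS["1"]) -> pd.DataFrame:
    """Reduce indices to canonical form and merge duplicates.

    Duplicate observations of one unique reflection are combined by the
    inverse-variance (1/σ²) weighted mean; the merged sigma is 1/sqrt(Σ 1/σ²).
    Groups containing σ = 0 observations fall back to the unweighted mean with
    merged σ = 0 (an exact observation dominates but cannot be divided by).
    """
    hkl = map_to_asu_array(df[["h", "k", "l"]].to_numpy(dtype=np.int64), ops)
    key = _encode_hkl(hkl)
    work = pd.DataFrame(
        {
            "key": key,
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "intensity": df["intensity"].to_numpy(dtype=float),
            "sigma": df["sigma"].to_numpy(dtype=float),
        }
    )

    def _combine(g: pd.DataFrame) -> pd.Series:
        if len(g) == 1:
            row = g.iloc[0]
            return pd.Series(
                {"h": row.h, "k": row.k, "l": row.l, "intensity": row.intensity, "sigma": row.sigma}
            )
        s = g["sigma"].to_numpy()
        i = g["intensity"].to_numpy()
        if np.any(s == 0):
            return pd.Series(
                {"h": g.iloc[0].h, "k": g.iloc[0].k, "l": g.iloc[0].l, "intensity": i.mean(), "sigma": 0.0}
            )
        w = 1.0 / s**2
        return pd.Series(
            {
                "h": g.iloc[0].h,
                "k": g.iloc[0].k,
                "l": g.iloc[0].l,
                "intensity": float(np.average(i, weights=w)),
                "sigma": float(1.0 / math.sqrt(w.sum())),
            }
        )

    if work["key"].is_unique:
        out = work.drop(columns="key")
    else:
        # fast path: merge only the duplicated keys, keep singletons as-is
        dup_mask = work.duplicated("key", keep=False)
        singles = work.loc[~dup_mask].drop(columns="key")
        merged = (
            work.loc[dup_mask]
            .groupby("key", sort=False)
            .apply(_combine, include_groups=False)
            .reset_index(drop=True)
        )
        out = pd.concat([singles, merged], ignore_index=True)
    out = out.astype({"h": np.int64, "k": np.int64, "l": np.int64})
    return out.sort_values(["h", "k", "l"], ignore_index=True)


# ---------------------------------------------------------------------------
# Readers / writers


def read_chunk_table(
    path,
    dialect: str = "tabular",
    *,
    chunk_id: str | None = None,
    crystal_id: str | None = None,
    cell: UnitCell | None = None,
    label: str | None = None,
) -> ReflectionChunk:
    """Read one chunk from a text file.

    ``tabular`` expects a header line ``h k l intensity sigma [frame]``; the
    ``xds_ascii`` dialect takes '!'-prefixed headers and requires
    ``!UNIT_CELL_CONSTANTS=`` (a tabular file instead needs ``cell`` passed
    in).  Duplicate (h, k, l) rows are merged by sigma-weighted mean.
    """
    path = Path(path)
    if dialect == "tabular":
        df, meta = _read_tabular(path)
        if cell is None:
            raise HeaderError(f"{path}: tabular dialect carries no cell; pass cell=")
    elif dialect == "xds_ascii":
        df, meta = _read_xds_ascii(path)
        cell = cell or meta.get("cell")
        if cell is None:
            raise HeaderError(f"{path}: missing !UNIT_CELL_CONSTANTS= header")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = merge_equivalents(df)
    return ReflectionChunk(
        chunk_id=chunk_id or path.stem,
        crystal_id=crystal_id or (chunk_id or path.stem),
        records=df,
        cell=cell,
        label=label,
    )


def _read_tabular(path: Path) -> tuple[pd.DataFrame, dict]:
    rows = []
    columns: list[str] | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if columns is None:
                columns = fields
                if list(columns[:5]) != list(_REQUIRED_COLUMNS):
                    raise ParseError(
                        f"{path}:{lineno}: header must start 'h k l intensity sigma'"
                    )
                continue
            if len(fields) != len(columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if columns is None:
        raise ParseError(f"{path}: empty file (no header)")
    df = pd.DataFrame(rows, columns=columns)
    df = df.astype({"h": np.int64, "k": np.int64, "l": np.int64})
    if "frame" in df.columns:
        df = df.astype({"frame": np.int64})
    return df, {}


def _read_xds_ascii(path: Path) -> tuple[pd.DataFrame, dict]:
    meta: dict = {}
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("!"):
                if line.startswith("!UNIT_CELL_CONSTANTS="):
                    try:
                        vals = [float(x) for x in line.split("=", 1)[1].split()]
                        meta["cell"] = UnitCell(*vals)
                    except (ValueError, TypeError) as exc:
                        raise HeaderError(f"{path}:{lineno}: bad unit-cell header: {exc}")
                elif line.startswith("!SPACE_GROUP_NUMBER="):
                    try:
                        meta["space_group_number"] = int(float(line.split("=", 1)[1]))
                    except ValueError as exc:
                        raise HeaderError(f"{path}:{lineno}: bad space-group header: {exc}")
                elif line.startswith("!END_OF_DATA"):
                    break
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected at least 5 fields")
            try:
                rows.append([float(x) for x in fields[:5]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS))
    df = df.astype({"h": np.int64, "k": np.int64, "l": np.int64})
    return df, meta


def write_chunk_table(chunk: ReflectionChunk, path) -> None:
    """Write a chunk in the tabular dialect (TSV, '#'-comment header)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# chunk_id={chunk.chunk_id} crystal_id={chunk.crystal_id}\n")
        fh.write("# cell=" + " ".join(f"{p:.4f}" for p in chunk.cell.parameters) + "\n")
        fh.write("h\tk\tl\tintensity\tsigma\n")
        for h, k, l, i, s in zip(
            *chunk.hkl.T, chunk.intensity, chunk.sigma
        ):
            fh.write(f"{h}\t{k}\t{l}\t{i:.6g}\t{s:.6g}\n")


def write_xds_ascii(chunk: ReflectionChunk, path, space_group_number: int = 19) -> None:
    """Write a chunk in the minimal XDS-ASCII dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!FORMAT=XDS_ASCII    MERGE=TRUE\n")
        fh.write(
            "!UNIT_CELL_CONSTANTS= "
            + " ".join(f"{p:.4f}" for p in chunk.cell.parameters)
            + "\n"
        )
        fh.write(f"!SPACE_GROUP_NUMBER= {space_group_number}\n")
        fh.write("!ITEM_H=1\n!ITEM_K=2\n!ITEM_L=3\n!ITEM_IOBS=4\n!ITEM_SIGMA(IOBS)=5\n")
        for h, k, l, i, s in zip(*chunk.hkl.T, chunk.intensity, chunk.sigma):
            fh.write(f"{h:6d}{k:6d}{l:6d} {i:14.6g} {s:14.6g}\n")
        fh.write("!END_OF_DATA\n")


# ---------------------------------------------------------------------------
# Angular partitioning


def split_into_chunks(
    records: pd.DataFrame,
    frame_width_deg: float,
    chunk_deg: float = 30.0,
    *,
    cell: UnitCell,
    crystal_id: str = "xtal",
    ops=POINT_GROUPS["1"],
    label: str | None = None,
) -> ChunkCollection:
    """Partition a frame-tagged observation stream into angular chunks.

    Frame f (1-based) covers rotation [(f-1)·w, f·w).  Chunk i receives the
    frames covering [i·chunk_deg, (i+1)·chunk_deg); within each chunk
    symmetry-equivalent observations are merged by sigma-weighted mean.  A
    trailing partial chunk narrower than chunk_deg/2 is discarded and flagged
    in the collection's provenance.
    """
    if "frame" not in records.columns or records["frame"].isna().any():
        raise ValueError("split_into_chunks requires a complete 'frame' column")
    if frame_width_deg <= 0:
        raise ValueError("frame_width_deg must be positive")
    ratio = chunk_deg / frame_width_deg
    if chunk_deg <= 0 or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("chunk_deg must be a positive multiple of frame_width_deg")
    frames_per_chunk = int(round(ratio))

    frames = records["frame"].to_numpy(dtype=np.int64)
    if (frames < 1).any():
        raise ValueError("frame numbers must be >= 1")
    chunk_index = (frames - 1) // frames_per_chunk

    n_frames_total = int(frames.max())
    last_index = int(chunk_index.max())
    discarded: list[int] = []
    # width actually covered by the trailing chunk, in degrees
    trailing_frames = n_frames_total - last_index * frames_per_chunk
    if trailing_frames * frame_width_deg < chunk_deg / 2 and last_index > 0:
        discarded.append(last_index)

    chunks: list[ReflectionChunk] = []
    n_obs_used = 0
    for idx in range(last_index + 1):
        sel = records.loc[chunk_index == idx]
        if idx in discarded or sel.empty:
            continue
        n_obs_used += len(sel)
        merged = merge_equivalents(sel[["h", "k", "l", "intensity", "sigma"]], ops)
        chunks.append(
            ReflectionChunk(
                chunk_id=f"{crystal_id}_c{idx:03d}",
                crystal_id=crystal_id,
                records=merged,
                cell=cell,
                rotation_start_deg=idx * chunk_deg,
                rotation_end_deg=(idx + 1) * chunk_deg,
                label=label,
            )
        )
    provenance = {
        "frame_width_deg": frame_width_deg,
        "chunk_deg": chunk_deg,
        "n_observations_in": int(len(records)),
        "n_observations_used": n_obs_used,
        "discarded_partial_chunks": discarded,
    }
    return ChunkCollection(chunks=chunks, provenance=provenance)
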