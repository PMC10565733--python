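"""Labelled synthetic reflection chunks with controlled CC structure.

Two latent "structures" are statistical stand-ins for two crystal polymorphs:
per-reflection intensities drawn from an exponential (Wilson acentric)
distribution, with the second structure a noisy mixture of the first so the
latent correlation is exactly a/sqrt(a² + 1) for mixing weight a.  Each chunk
observes a uniform-random subset of the unique reflections (modelling
per-chunk completeness) with additive Gaussian noise sized so that two chunks
of one structure correlate at the target within-structure CC:

    observed within-CC  = Var(I) / (Var(I) + σ_n²)        → σ_n from ρ_w
    observed between-CC = ρ_latent · ρ_w                  → ρ_latent = ρ_b/ρ_w

Defaults emulate the chunked helical trypsin mixture this package's threshold
calibration is built around: ~50 000 unique reflections, 40% per-chunk
completeness, within-structure CC 0.97, between-structure CC 0.96, 48 chunks
per structure (four crystals × twelve 30° chunks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cell import UnitCell
from .reflections import ChunkCollection, ReflectionChunk, write_chunk_table

__all__ = [
    "SynthSpec",
    "SynthDataset",
    "generate_hkl_set",
    "generate_structures",
    "observe_chunk",
    "generate_dataset",
]

#: orthorhombic trypsin-like cell (P2₁2₁2₁ setting)
_DEFAULT_CELL = UnitCell(54.7, 58.5, 67.4, 90.0, 90.0, 90.0)


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters; defaults are the chunked-trypsin study conditions."""

    n_unique: int = 50_000
    completeness: float = 0.4
    rho_within: float = 0.97
    rho_between: float = 0.96
    n_chunks_per_group: int = 48
    cell: UnitCell = _DEFAULT_CELL
    cell_jitter_percent: float = 0.05
    chunk_deg: float = 30.0
    chunks_per_crystal: int = 12  # 360° helical sweep at 30° per chunk
    mean_intensity: float = 1000.0
    tip_noise_multiplier: float = 1.0  # >1 emulates degraded crystal-tip chunks
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must lie in (0, 1]")
        if not 0.0 < self.rho_between <= self.rho_within <= 1.0:
            raise ValueError("require 0 < rho_between <= rho_within <= 1")
        if self.completeness * self.n_unique < 10:
            raise ValueError("completeness * n_unique must be >= 10")


@dataclass
class SynthDataset:
    """Generated chunks plus ground truth for scoring."""

    chunks: ChunkCollection
    spec: SynthSpec

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.chunks]

    def pair_class(self, i: int, j: int) -> str:
        """Expected CC class of a chunk pair: within_a / within_b / between."""
        la, lb = self.chunks[i].label, self.chunks[j].label
        if la == lb:
            return "within_a" if la == "A" else "within_b"
        return "between"

    def write(self, outdir) -> None:
        """Emit tabular chunk files plus a labels TSV (chunk_id, group)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for chunk in self.chunks:
            write_chunk_table(chunk, outdir / f"{chunk.chunk_id}.tsv")
        with open(outdir / "labels.tsv", "w", encoding="utf-8") as fh:
            fh.write("chunk_id\tgroup\n")
            for chunk in self.chunks:
                fh.write(f"{chunk.chunk_id}\t{chunk.label}\n")


def generate_hkl_set(cell: UnitCell, n_unique: int) -> np.ndarray:
    """Deterministic set of n_unique half-sphere Miller indices, lowest
    resolution shells first (sorted by descending d-spacing)."""
    hmax = max(2, math.ceil((4.0 * n_unique) ** (1.0 / 3.0) / 2.0) + 2)
    rng_axis = np.arange(-hmax, hmax + 1)
    h, k, l = np.meshgrid(np.arange(0, hmax + 1), rng_axis, rng_axis, indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    # unique under Friedel: keep h>0, or h=0 & k>0, or h=k=0 & l>0
    keep = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | (
        (hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)
    )
    hkl = hkl[keep]
    if len(hkl) < n_unique:
        raise ValueError("internal: index grid too small")
    d = cell.d_spacing(hkl[:, 0], hkl[:, 1], hkl[:, 2])
    order = np.argsort(-d, kind="stable")
    return hkl[order[:n_unique]]


def generate_structures(spec: SynthSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Latent intensity vectors of the two structures over n_unique indices.

    I_A ~ Exponential(mean Σ); I_B = (a·I_A + I')/(a + 1) with I' independent
    Exponential(Σ), giving corr(I_A, I_B) = a/sqrt(a² + 1) exactly.  Under the
    additive observation noise of :func:`observe_chunk`, the observed
    between-chunk CC is ρ_latent·ρ_w, so the required latent correlation has
    the closed form ρ_latent = ρ_b/ρ_w and a = ρ_latent/sqrt(1 - ρ_latent²).
    """
    sigma = spec.mean_intensity
    I_A = rng.exponential(sigma, size=spec.n_unique)
    rho_latent = spec.rho_between / spec.rho_within
    if rho_latent >= 1.0:
        return I_A, I_A.copy()
    a = rho_latent / math.sqrt(1.0 - rho_latent**2)
    I_prime = rng.exponential(sigma, size=spec.n_unique)
    I_B = (a * I_A + I_prime) / (a + 1.0)
    return I_A, I_B


def _noise_sd(structure_I: np.ndarray, rho_within: float) -> float:
    if rho_within >= 1.0:
        return 0.0
    var = float(np.var(structure_I))
    return math.sqrt(var * (1.0 - rho_within) / rho_within)


def observe_chunk(
    structure_I: np.ndarray,
    hkl: np.ndarray,
    spec: SynthSpec,
    chunk_id: str,
    crystal_id: str,
    label: str,
    chunk_index: int,
    rng: np.random.Generator,
    noise_multiplier: float = 1.0,
) -> ReflectionChunk:
    """Observe one chunk: random index subset + additive Gaussian noise.

    The subset size is completeness·n_unique; σ_n is set from the target
    within-structure CC (σ_n² = Var(I)(1-ρ_w)/ρ_w) and recorded as the
    per-reflection sigma.  Cell lengths are jittered by cell_jitter_percent.
    """
    n = len(structure_I)
    n_obs = int(round(spec.completeness * n))
    if n_obs < 10:
        raise ValueError("chunk would contain fewer than 10 reflections")
    sel = rng.choice(n, size=n_obs, replace=False)
    sel.sort()
    sd = _noise_sd(structure_I, spec.rho_within) * noise_multiplier
    intensity = structure_I[sel] + (rng.normal(0.0, sd, size=n_obs) if sd > 0 else 0.0)
    jitter = spec.cell_jitter_percent / 100.0
    cell = UnitCell(
        spec.cell.a * (1.0 + rng.normal(0.0, jitter)),
        spec.cell.b * (1.0 + rng.normal(0.0, jitter)),
        spec.cell.c * (1.0 + rng.normal(0.0, jitter)),
        spec.cell.alpha,
        spec.cell.beta,
        spec.cell.gamma,
    )
    records = pd.DataFrame(
        {
            "h": hkl[sel, 0],
            "k": hkl[sel, 1],
            "l": hkl[sel, 2],
            "intensity": intensity,
            "sigma": np.full(n_obs, sd),
        }
    )
    start = (chunk_index % int(360.0 / spec.chunk_deg)) * spec.chunk_deg
    return ReflectionChunk(
        chunk_id=chunk_id,
        crystal_id=crystal_id,
        records=records,
        cell=cell,
        rotation_start_deg=start,
        rotation_end_deg=start + spec.chunk_deg,
        label=label,
    )


def generate_dataset(spec: SynthSpec) -> SynthDataset:
    """Both structures, n_chunks_per_group chunks each, deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    hkl = generate_hkl_set(spec.cell, spec.n_unique)
    I_A, I_B = generate_structures(spec, rng)
    chunks: list[ReflectionChunk] = []
    for label, structure in (("A", I_A), ("B", I_B)):
        for i in range(spec.n_chunks_per_group):
            crystal = f"{label}{i // spec.chunks_per_crystal}"
            chunks.append(
                observe_chunk(
                    structure,
                    hkl,
                    spec,
                    chunk_id=f"{label}_{i:03d}",
                    crystal_id=crystal,
                    label=label,
                    chunk_index=i,
                    rng=rng,
                    noise_multiplier=spec.tip_noise_multiplier
                    if (i % spec.chunks_per_crystal) == spec.chunks_per_crystal - 1
                    and spec.tip_noise_multiplier != 1.0
                    else 1.0,
                )
            )
    collection = ChunkCollection(
        chunks=chunks,
        provenance={"generator": "isoclust.synth", "seed": spec.seed},
    )
    return SynthDataset(chunks=collection, spec=spec)
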