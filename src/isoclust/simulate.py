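"""Monte-Carlo calibration of the isomorphic-threshold ratio R.

The observed pairwise-CC distributions of a two-structure chunk mixture are
summarised by three Gaussian components (within-A, within-B, between), each a
(median, SD) pair fitted to CC samples after discarding the low-CC tail
(d_CC >= 0.4, i.e. CC <= ~0.9165).  Synthetic CC matrices drawn pair-by-pair
from that model are clustered with Ward linkage on d_CC; each replicate yields
W0, W1, the observed ratio R = W1/W0, and a two-cut classification score
against the true group labels.

The *approach sweep* then degrades the model stepwise — the between-structure
median moves linearly toward the within-B median until the two distributions
coincide — across a range of data-set counts, mapping out where classification
(score >= 0.9) stops being possible and hence which ratio R is safe to use as
the isomorphic threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .correlation import DistanceMatrix, cc_to_distance
from .errors import FitError
from .hca import classification_score, linkage_cluster

__all__ = [
    "GaussianPeak",
    "CCModel",
    "TRYPSIN_MODEL",
    "SimulationResult",
    "SweepPoint",
    "SweepResult",
    "RatioInterval",
    "fit_cc_model",
    "sample_cc_matrix",
    "run_simulation",
    "summarize_w1",
    "approach_sweep",
    "recommend_ratio",
]

_CC_CLIP = 1.0 - 1e-6  # keep Gaussian tails off |CC| = 1 (zero-distance degeneracy)


class GaussianPeak(NamedTuple):
    """Location/scale of one CC distribution (median used as the Gaussian mean)."""

    median: float
    sd: float


@dataclass(frozen=True)
class CCModel:
    """Three-component Gaussian model of pairwise CC distributions."""

    within_a: GaussianPeak
    within_b: GaussianPeak
    between: GaussianPeak
    dcc_fit_cutoff: float = 0.4

    def __post_init__(self) -> None:
        for name in ("within_a", "within_b", "between"):
            peak = getattr(self, name)
            if not -1.0 < peak.median < 1.0:
                raise ValueError(f"{name} median must lie in (-1, 1)")
            if peak.sd < 0:
                raise ValueError(f"{name} sd must be non-negative")


#: CC model fitted to the apo / benzamidine-bound trypsin 30° chunk mixture
#: (medians and SDs of the within-apo, within-benz and apo-benz CC peaks).
TRYPSIN_MODEL = CCModel(
    within_a=GaussianPeak(0.978, 0.020),
    within_b=GaussianPeak(0.970, 0.019),
    between=GaussianPeak(0.962, 0.017),
)


@dataclass(frozen=True)
class SimulationResult:
    replicate: int
    W0: float
    W1: float
    R_obs: float
    score: float


@dataclass(frozen=True)
class SweepPoint:
    overlap_step: int
    n_datasets: int
    mean_R: float
    mean_score: float


@dataclass
class SweepResult:
    points: list[SweepPoint]
    steps: int
    n_list: tuple[int, ...]
    replicates: int

    def __iter__(self):
        return iter(self.points)


@dataclass(frozen=True)
class RatioInterval:
    """Recommended R interval; empty (low/high None) carries a diagnostic."""

    low: float | None
    high: float | None
    diagnostic: str = ""

    @property
    def empty(self) -> bool:
        return self.low is None


def fit_cc_model(
    cc_within_a: Sequence[float],
    cc_within_b: Sequence[float],
    cc_between: Sequence[float],
    dcc_fit_cutoff: float = 0.4,
) -> CCModel:
    """Fit the three-peak model from CC samples.

    Each sample set is restricted to its prominent peak, d_CC < cutoff
    (CC > sqrt(1 - cutoff²)); the peak is summarised by its median and sample
    standard deviation.
    """
    cc_min = math.sqrt(1.0 - dcc_fit_cutoff**2)
    peaks = []
    for name, sample in (
        ("within_a", cc_within_a),
        ("within_b", cc_within_b),
        ("between", cc_between),
    ):
        arr = np.asarray(sample, dtype=float)
        arr = arr[arr > cc_min]
        if arr.size == 0:
            raise FitError(f"no {name} CC samples survive the d_CC < {dcc_fit_cutoff} filter")
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        peaks.append(GaussianPeak(float(np.median(arr)), sd))
    return CCModel(*peaks, dcc_fit_cutoff=dcc_fit_cutoff)


def sample_cc_matrix(
    model: CCModel,
    n_a: int,
    n_b: int,
    seed,
    metric: str = "sqrt_one_minus_cc2",
) -> tuple[DistanceMatrix, np.ndarray]:
    """Draw one symmetric CC matrix from the model and transform to distances.

    Each unordered pair receives an independent Gaussian CC draw from its
    pair class; draws are clipped to ±(1 - 1e-6).  Returns the distance
    matrix and the ground-truth group labels ('A'/'B') for scoring.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 members per group")
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    labels = np.array(["A"] * n_a + ["B"] * n_b)
    is_a = labels == "A"

    mean = np.empty((n, n))
    sd = np.empty((n, n))
    same_a = np.outer(is_a, is_a)
    same_b = np.outer(~is_a, ~is_a)
    mean[same_a], sd[same_a] = model.within_a
    mean[same_b], sd[same_b] = model.within_b
    cross = ~(same_a | same_b)
    mean[cross], sd[cross] = model.between

    cc = rng.normal(mean, sd)
    iu = np.triu_indices(n, k=1)
    sym = np.zeros((n, n))
    sym[iu] = np.clip(cc[iu], -_CC_CLIP, _CC_CLIP)
    sym += sym.T
    dist = cc_to_distance(sym, metric)
    np.fill_diagonal(dist, 0.0)
    ids = [f"A{i:03d}" for i in range(n_a)] + [f"B{i:03d}" for i in range(n_b)]
    return DistanceMatrix(labels=ids, values=dist), labels


def run_simulation(
    model: CCModel,
    n_a: int = 42,
    n_b: int = 41,
    replicates: int = 100,
    seed: int = 0,
    linkage: str = "ward",
) -> list[SimulationResult]:
    """Replicate sample → Ward → (W0, W1, R, score) with derived child seeds."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    children = np.random.SeedSequence(seed).spawn(replicates)
    out: list[SimulationResult] = []
    for r, child in enumerate(children):
        D, labels = sample_cc_matrix(model, n_a, n_b, child)
        tree = linkage_cluster(D, linkage)
        W0, W1 = tree.W0, tree.W1
        score = classification_score(tree, labels, k=2)
        out.append(SimulationResult(r, W0, W1, W1 / W0 if W0 > 0 else 0.0, score))
    return out


def summarize_w1(results: list[SimulationResult]) -> dict:
    """Mean/SD of W0, W1, R and score over replicates."""
    w0 = np.array([r.W0 for r in results])
    w1 = np.array([r.W1 for r in results])
    rr = np.array([r.R_obs for r in results])
    sc = np.array([r.score for r in results])
    return {
        "replicates": len(results),
        "mean_W0": float(w0.mean()),
        "mean_W1": float(w1.mean()),
        "sd_W1": float(w1.std(ddof=1)) if len(results) > 1 else 0.0,
        "mean_R": float(rr.mean()),
        "mean_score": float(sc.mean()),
        "min_score": float(sc.min()),
    }


def interpolate_between(model: CCModel, frac: float) -> CCModel:
    """Move the between-structure median toward the within-B median.

    frac = 0 returns the model unchanged; frac = 1 makes the two locations
    coincide (classification impossible in expectation).
    """
    if not 0.0 <= frac <= 1.0:
        raise ValueError("frac must lie in [0, 1]")
    m = model.between.median + frac * (model.within_b.median - model.between.median)
    return replace(model, between=GaussianPeak(m, model.between.sd))


def approach_sweep(
    model: CCModel,
    steps: int = 10,
    n_list: Sequence[int] = (100, 200, 300, 500, 1000),
    replicates: int = 10,
    seed: int = 0,
) -> SweepResult:
    """Degrade the model stepwise and record mean R and score per (step, n).

    Step s (0..steps-1) moves the between-structure median linearly toward
    the within-B median by the fraction s/(steps-1); step 0 is the fitted
    model, the final step has the two distributions coincident in location.
    Groups are balanced (n//2 and n - n//2).
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    points: list[SweepPoint] = []
    top = np.random.SeedSequence(seed).spawn(steps * len(n_list))
    idx = 0
    for s in range(steps):
        model_s = interpolate_between(model, s / (steps - 1))
        for n in n_list:
            child_seed = int(top[idx].generate_state(1)[0] % (2**31))
            idx += 1
            res = run_simulation(model_s, n // 2, n - n // 2, replicates, child_seed)
            summ = summarize_w1(res)
            points.append(SweepPoint(s, int(n), summ["mean_R"], summ["mean_score"]))
    return SweepResult(points=points, steps=steps, n_list=tuple(int(n) for n in n_list),
                       replicates=replicates)


def recommend_ratio(
    sweep: SweepResult,
    score_threshold: float = 0.9,
    n_max: int = 500,
) -> RatioInterval:
    """Largest observed-R interval still classifying successfully.

    Considers sweep points with n <= n_max (the "several hundred data sets"
    regime) whose mean score clears the threshold, and returns the interval
    spanned by their mean R values.
    """
    if not sweep.points:
        raise ValueError("sweep is empty")
    passing = [
        p for p in sweep.points if p.n_datasets <= n_max and p.mean_score >= score_threshold
    ]
    if not passing:
        return RatioInterval(
            None, None, f"no sweep point with n <= {n_max} reached score {score_threshold}"
        )
    rs = [p.mean_R for p in passing]
    return RatioInterval(min(rs), max(rs))
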