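"""Agglomerative clustering, the isomorphic threshold, and cluster scoring.

The dendrogram height at which two branches merge measures how non-isomorphous
their members are.  Two quantities drive polymorph nomination:

* W0 — the maximum merge height (the root of the dendrogram);
* W1 — the larger height of the root's two children.

The *isomorphic threshold* is R·W0 with R a calibrated ratio (0.6–0.7 for
several hundred data sets); maximal nodes whose height falls at or below the
threshold are nominated as polymorph candidates, with very small clusters set
aside as outliers.  Ward linkage on d_CC = (1 - CC²)^1/2 is the default,
following the practice of the multi-crystal merging pipelines this package
models itself on; all seven standard Lance–Williams linkages are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.optimize import linear_sum_assignment

from .correlation import DistanceMatrix

__all__ = [
    "Dendrogram",
    "PolymorphReport",
    "LINKAGE_METHODS",
    "linkage_cluster",
    "extract_w0_w1",
    "isomorphic_threshold",
    "nominate_polymorphs",
    "classification_score",
]

LINKAGE_METHODS = ("single", "complete", "average", "weighted", "centroid", "median", "ward")
# centroid/median can produce non-monotone merge heights (inversions)
_INVERTING = {"centroid", "median"}


@dataclass
class Dendrogram:
    """Binary merge tree over labelled leaves.

    ``Z`` is the (n-1, 4) scipy linkage matrix: leaves are nodes 0..n-1 at
    height 0; internal node n+j merges Z[j,0] and Z[j,1] at height Z[j,2].
    """

    Z: np.ndarray
    labels: list[str]
    method: str

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.labels)
        if self.Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape inconsistent with labels")
        self._members: dict[int, frozenset[int]] = {}

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root_id(self) -> int:
        return 2 * self.n_leaves - 2

    def height(self, node_id: int) -> float:
        n = self.n_leaves
        return 0.0 if node_id < n else float(self.Z[node_id - n, 2])

    def children(self, node_id: int) -> tuple[int, int] | None:
        n = self.n_leaves
        if node_id < n:
            return None
        row = self.Z[node_id - n]
        return int(row[0]), int(row[1])

    def members(self, node_id: int) -> frozenset[int]:
        """Leaf indices under a node (iterative; cached)."""
        if node_id in self._members:
            return self._members[node_id]
        n = self.n_leaves
        out: list[int] = []
        stack = [node_id]
        while stack:
            nid = stack.pop()
            if nid < n:
                out.append(nid)
            else:
                stack.extend(self.children(nid))
        res = frozenset(out)
        self._members[node_id] = res
        return res

    @property
    def W0(self) -> float:
        """Maximum merge height (root of the dendrogram)."""
        return float(self.Z[-1, 2])

    @property
    def W1(self) -> float:
        """Larger height of the root's two children (0 for leaf children)."""
        a, b = self.children(self.root_id)
        return max(self.height(a), self.height(b))

    @property
    def has_inversions(self) -> bool:
        heights = self.Z[:, 2]
        child_heights = np.array(
            [max(self.height(int(r[0])), self.height(int(r[1]))) for r in self.Z]
        )
        return bool(np.any(heights < child_heights - 1e-12))

    def flat_clusters(self, k: int) -> np.ndarray:
        """Cut at the k-1 highest merges into k flat clusters (1..k labels)."""
        if not 2 <= k <= self.n_leaves:
            raise ValueError("k must lie in [2, n_leaves]")
        return sch.fcluster(self.Z, t=k, criterion="maxclust")

    # -- exports -----------------------------------------------------------

    def to_dict(self) -> dict:
        nodes = []
        for nid in range(2 * self.n_leaves - 1):
            ch = self.children(nid)
            nodes.append(
                {
                    "node_id": nid,
                    "children": list(ch) if ch else [],
                    "height": self.height(nid),
                    "members": sorted(self.labels[i] for i in self.members(nid)),
                }
            )
        return {
            "linkage": self.method,
            "W0": self.W0,
            "W1": self.W1,
            "root_id": self.root_id,
            "nodes": nodes,
        }

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""

        def rec(nid: int, parent_h: float) -> str:
            h = self.height(nid)
            bl = max(parent_h - h, 0.0)
            ch = self.children(nid)
            if ch is None:
                return f"{self.labels[nid]}:{bl:.10g}"
            return f"({rec(ch[0], h)},{rec(ch[1], h)}):{bl:.10g}"

        return rec(self.root_id, self.W0) + ";"


@dataclass
class PolymorphReport:
    """Clusters nominated below the isomorphic threshold.

    candidate_clusters are (node_id, member chunk_ids, height); outliers are
    below-threshold nodes too small to trust (member count under
    min_cluster_fraction of the leaves).
    """

    threshold_interval: tuple[float, float]
    candidate_clusters: list[tuple[int, list[str], float]]
    outliers: list[tuple[int, list[str], float]]
    W0: float
    W1: float
    R_interval: tuple[float, float] = (0.6, 0.7)

    def to_dict(self) -> dict:
        return {
            "W0": self.W0,
            "W1": self.W1,
            "R_interval": list(self.R_interval),
            "threshold_interval": list(self.threshold_interval),
            "candidates": [
                {"node_id": nid, "members": m, "height": h}
                for nid, m, h in self.candidate_clusters
            ],
            "outliers": [
                {"node_id": nid, "members": m, "height": h}
                for nid, m, h in self.outliers
            ],
        }


def linkage_cluster(D: DistanceMatrix, method: str = "ward") -> Dendrogram:
    """Agglomerate a distance matrix with any of the seven standard linkages.

    The matrix is treated as a plain dissimilarity (Ward's Euclidean
    assumption is not enforced, matching common crystallographic practice).
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage {method!r}; choose one of {LINKAGE_METHODS}")
    if len(D) < 3:
        raise ValueError("need at least 3 items to cluster")
    cond = D.condensed()
    if not np.all(np.isfinite(cond)):
        raise ValueError("distance matrix contains non-finite entries")
    Z = sch.linkage(cond, method=method)
    return Dendrogram(Z=Z, labels=list(D.labels), method=method)


def extract_w0_w1(tree: Dendrogram) -> tuple[float, float]:
    """(W0, W1): root height and the larger child-of-root height."""
    if tree.n_leaves < 2:
        raise ValueError("W0/W1 require at least two leaves")
    return tree.W0, tree.W1


def isomorphic_threshold(W0: float, R: float) -> float:
    """Threshold W1 = R·W0; R must be a ratio strictly inside (0, 1)."""
    if not 0.0 < R < 1.0:
        raise ValueError("R must lie strictly in (0, 1)")
    if W0 < 0:
        raise ValueError("W0 must be non-negative")
    return R * W0


def nominate_polymorphs(
    tree: Dendrogram,
    R_low: float = 0.6,
    R_high: float = 0.7,
    min_cluster_fraction: float = 0.05,
) -> PolymorphReport:
    """Nominate maximal nodes at or below the isomorphic threshold R_high·W0.

    Descends from the root; a node whose height <= threshold is taken whole
    (maximal-node semantics), otherwise its children are examined.  Nodes with
    fewer than min_cluster_fraction·n leaves are reported as outliers rather
    than candidates.  An empty candidate list means "no polymorphs detected".
    """
    if not 0.0 < R_low <= R_high < 1.0:
        raise ValueError("require 0 < R_low <= R_high < 1")
    W0 = tree.W0
    thr = R_high * W0
    n = tree.n_leaves
    min_size = min_cluster_fraction * n

    candidates: list[tuple[int, list[str], float]] = []
    outliers: list[tuple[int, list[str], float]] = []
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        h = tree.height(nid)
        if h <= thr:
            members = sorted(tree.labels[i] for i in tree.members(nid))
            entry = (nid, members, h)
            if len(members) < min_size:
                outliers.append(entry)
            else:
                candidates.append(entry)
        else:
            stack.extend(tree.children(nid))
    candidates.sort(key=lambda t: t[0])
    outliers.sort(key=lambda t: t[0])
    return PolymorphReport(
        threshold_interval=(R_low * W0, R_high * W0),
        candidate_clusters=candidates,
        outliers=outliers,
        W0=W0,
        W1=tree.W1,
        R_interval=(R_low, R_high),
    )


def classification_score(
    tree: Dendrogram, labels: Sequence, k: int = 2
) -> float:
    """Best-assignment accuracy of a k-way flat cut against true labels.

    The tree is cut at its k-1 highest merges; the score is the fraction of
    leaves correctly labelled under the best injective mapping of flat
    clusters onto true labels (Hungarian assignment on the contingency table).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > tree.n_leaves:
        raise ValueError("k exceeds the number of leaves")
    labels = np.asarray(labels)
    if len(labels) != tree.n_leaves:
        raise ValueError("labels must cover all leaves")
    flat = tree.flat_clusters(k)
    cats = np.unique(labels)
    contingency = np.zeros((k, len(cats)), dtype=int)
    for ci in range(1, k + 1):
        mask = flat == ci
        for gi, g in enumerate(cats):
            contingency[ci - 1, gi] = int(np.sum(mask & (labels == g)))
    rows, cols = linear_sum_assignment(-contingency)
    return float(contingency[rows, cols].sum()) / tree.n_leaves
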