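"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library paths they check: the agglomeration
oracle is a direct O(n^3) Lance-Williams recursion over explicit pair
dictionaries, not a call into scipy.
"""

import numpy as np

LW_METHODS = ("single", "complete", "average", "weighted", "centroid", "median", "ward")


def brute_force_linkage(Dfull: np.ndarray, method: str):
    """Agglomerate a full square distance matrix step by step.

    Returns the merge list [(height, frozenset(member leaf indices)), ...] in
    merge order.  Ward/centroid/median recursions run on squared distances,
    with heights reported as square roots, matching the standard convention
    for distance input.
    """
    n = Dfull.shape[0]
    sq = method in ("ward", "centroid", "median")
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = Dfull[i, j] ** 2 if sq else Dfull[i, j]
    members = {i: frozenset([i]) for i in range(n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    nxt = n
    while len(active) > 1:
        (i, j), dij = min(
            ((p, d) for p, d in dist.items() if p[0] in active and p[1] in active),
            key=lambda t: (t[1], t[0]),
        )
        merges.append((np.sqrt(dij) if sq else dij, members[i] | members[j]))
        ni, nj = size[i], size[j]
        for o in active - {i, j}:
            dio = dist[tuple(sorted((i, o)))]
            djo = dist[tuple(sorted((j, o)))]
            no = size[o]
            if method == "single":
                d = min(dio, djo)
            elif method == "complete":
                d = max(dio, djo)
            elif method == "average":
                d = (ni * dio + nj * djo) / (ni + nj)
            elif method == "weighted":
                d = 0.5 * (dio + djo)
            elif method == "ward":
                d = ((ni + no) * dio + (nj + no) * djo - no * dij) / (ni + nj + no)
            elif method == "centroid":
                d = (ni * dio + nj * djo) / (ni + nj) - ni * nj * dij / (ni + nj) ** 2
            elif method == "median":
                d = 0.5 * dio + 0.5 * djo - 0.25 * dij
            else:
                raise ValueError(method)
            dist[tuple(sorted((nxt, o)))] = d
        members[nxt] = members[i] | members[j]
        size[nxt] = ni + nj
        active -= {i, j}
        active.add(nxt)
        nxt += 1
    return merges


def random_distance_matrix(rng, n=8, euclidean=False):
    """A random symmetric zero-diagonal matrix (optionally a true metric)."""
    if euclidean:
        X = rng.random((n, 3))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
    else:
        D = rng.random((n, n))
        D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


def merges_from_dendrogram(tree):
    """Extract the (height, member-set) merge list from a Dendrogram."""
    n = tree.n_leaves
    out = []
    for r in range(n - 1):
        out.append((float(tree.Z[r, 2]), tree.members(n + r)))
    return out
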