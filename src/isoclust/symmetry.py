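"""Point-group reduction of Miller indices.

Chunked output from integration pipelines normally arrives already reduced to
the asymmetric unit, so the default operator set is the identity.  Built-in
rotation sets are provided for point groups 2 (monoclinic, b-unique) and 222
(orthorhombic), which cover the common low-symmetry macromolecular space
groups (C2, P2₁2₁2₁).  Friedel inversion is always applied, so the canonical
index of (h, k, l) and (-h, -k, -l) coincide.
"""

from __future__ import annotations

import numpy as np

__all__ = ["POINT_GROUPS", "map_to_asu", "map_to_asu_array"]

_I = np.eye(3, dtype=int)

POINT_GROUPS: dict[str, list[np.ndarray]] = {
    "1": [_I],
    # 2-fold along b
    "2": [_I, np.diag([-1, 1, -1])],
    # three mutually perpendicular 2-folds
    "222": [_I, np.diag([1, -1, -1]), np.diag([-1, 1, -1]), np.diag([-1, -1, 1])],
}


def _check_ops(ops) -> list[np.ndarray]:
    ops = [np.asarray(op, dtype=int) for op in ops]
    if not ops:
        raise ValueError("operator list must be non-empty (include the identity)")
    if not any(np.array_equal(op, _I) for op in ops):
        raise ValueError("operator list must contain the identity")
    return ops


def map_to_asu(hkl, ops=POINT_GROUPS["1"]):
    """Canonical (lexicographically greatest) image of one index triple.

    The orbit comprises every rotation image and its Friedel mate; picking the
    lexicographic maximum makes the map deterministic, idempotent and constant
    on orbits.
    """
    out = map_to_asu_array(np.asarray(hkl, dtype=int).reshape(1, 3), ops)
    return tuple(int(x) for x in out[0])


def map_to_asu_array(hkl: np.ndarray, ops=POINT_GROUPS["1"]) -> np.ndarray:
    """Vectorised canonical reduction of an (N, 3) index array."""
    ops = _check_ops(ops)
    hkl = np.asarray(hkl, dtype=int)
    images = np.stack([hkl @ op.T for op in ops], axis=0)
    images = np.concatenate([images, -images], axis=0)  # Friedel mates
    # lexicographic argmax over the image axis: compare h, then k, then l
    order = np.lexsort((images[..., 2], images[..., 1], images[..., 0]), axis=0)
    best = order[-1]
    return np.take_along_axis(images, best[None, :, None], axis=0)[0]
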