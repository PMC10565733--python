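"""Triclinic unit cells and resolution (d-spacing) arithmetic.

The cell is the general triclinic parallelepiped (a, b, c in Å; α, β, γ in
degrees).  Resolution of a reflection (h, k, l) is computed from the
reciprocal metric tensor, d = 1/sqrt(hᵀ G* h), which specialises to the
familiar closed forms for the higher-symmetry systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["UnitCell"]


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell constants: lengths in Å, angles in degrees.

    Invariants enforced at construction: all lengths positive, all angles in
    (0, 180)°, and the metric tensor positive definite (i.e. the three angles
    describe a realisable parallelepiped).
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180) degrees")
        try:
            np.linalg.cholesky(self.metric_tensor())
        except np.linalg.LinAlgError:
            raise ValueError("cell angles do not define a positive-definite metric")

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (Å²)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G⁻¹ (Å⁻²)."""
        return np.linalg.inv(self.metric_tensor())

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        return float(np.sqrt(np.linalg.det(self.metric_tensor())))

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    @property
    def parameters(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def d_spacing(self, h, k, l):
        """Resolution d (Å) of reflection(s) (h, k, l).

        Accepts scalars or equal-length arrays.  Raises for the null triple
        (0, 0, 0), which has no Bragg spacing.
        """
        hkl = np.stack(np.broadcast_arrays(h, k, l), axis=-1).astype(float)
        if np.any(~hkl.any(axis=-1)):
            raise ValueError("d-spacing undefined for the (0,0,0) index triple")
        gstar = self.reciprocal_metric_tensor()
        inv_d2 = np.einsum("...i,ij,...j->...", hkl, gstar, hkl)
        out = 1.0 / np.sqrt(inv_d2)
        return float(out) if out.ndim == 0 else out
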