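"""Natural cubic spline bases NS(x, df) for the time and temperature smooths.

These are fixed-df regression splines (no smoothing penalty): flexibility
is indexed entirely by ``df``, the number of basis columns excluding the
intercept.  Interior knots sit at equally spaced quantiles of the distinct
observed predictor values and boundary knots at the observed range, so the
data and ``df`` fully determine the basis.  Beyond the boundary knots every
basis function continues linearly (the "natural" constraint of zero second
derivative), which is what makes time-spline extrapolation into a forecast
window well behaved.

Construction follows the classical recipe: start from the cubic B-spline
design on the knot sequence, then restrict to the subspace satisfying the
two natural boundary constraints via a QR factorisation of the constraint
matrix.  Columns are centered on the training sample so the level is
absorbed by the model intercept; centering never changes fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass
class NaturalSplineBasis:
    """Natural cubic spline basis with ``df`` columns (intercept excluded)."""

    df: int
    boundary_knots: np.ndarray
    interior_knots: np.ndarray
    # transform from the (df+3) B-spline columns to df natural columns
    _transform: np.ndarray = field(repr=False)
    _center: np.ndarray = field(repr=False)

    @property
    def knots(self) -> np.ndarray:
        """Full padded knot vector for the underlying cubic B-splines."""
        a, b = self.boundary_knots
        return np.r_[[a] * 4, self.interior_knots, [b] * 4]

    def design(self, x, center: bool = True) -> np.ndarray:
        """Evaluate the basis at ``x`` (n × df), linear beyond the boundary."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        a, b = self.boundary_knots
        inside = np.clip(x, a, b)
        B = BSpline.design_matrix(inside, self.knots, 3).toarray()
        G = B @ self._transform

        lo, hi = x < a, x > b
        if lo.any() or hi.any():
            for mask, knot in ((lo, a), (hi, b)):
                if not mask.any():
                    continue
                val = self._raw_at(np.array([knot]))
                der = self._raw_deriv_at(np.array([knot]))
                G[mask] = val + (x[mask, None] - knot) * der
        if center:
            G = G - self._center
        return G

    def _raw_at(self, pts: np.ndarray) -> np.ndarray:
        B = BSpline.design_matrix(pts, self.knots, 3).toarray()
        return B @ self._transform

    def _raw_deriv_at(self, pts: np.ndarray, nu: int = 1) -> np.ndarray:
        n_b = len(self.interior_knots) + 4
        cols = []
        for j in range(n_b):
            c = np.zeros(n_b)
            c[j] = 1.0
            cols.append(BSpline(self.knots, c, 3)(pts, nu=nu))
        return np.column_stack(cols) @ self._transform

    def derivative(self, x, nu: int = 1) -> np.ndarray:
        """Derivative of each basis column at ``x`` (constant slope outside
        the boundary for nu=1, zero for nu=2)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        a, b = self.boundary_knots
        inside = np.clip(x, a, b)
        D = self._raw_deriv_at(inside, nu=nu)
        out = (x < a) | (x > b)
        if out.any() and nu >= 2:
            D[out] = 0.0
        return D

    def evaluate(self, coef, x_new) -> np.ndarray:
        """Fitted smooth Σ_j coef_j N_j(x) at new points."""
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (self.df,):
            raise ValueError(f"coef must have length df={self.df}")
        return self.design(x_new) @ coef


def build_basis(x, df: int) -> NaturalSplineBasis:
    """Construct NS(x, df) with quantile interior knots and range boundary
    knots.

    ``df`` counts basis columns excluding the intercept, so df=1 is a single
    column affine in x and df=k uses k−1 interior knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    distinct = np.unique(x[np.isfinite(x)])
    if distinct.size < df + 1:
        raise ValueError(
            f"df={df} needs at least {df + 1} distinct values, "
            f"got {distinct.size}"
        )
    a, b = distinct[0], distinct[-1]
    if df > 1:
        probs = np.arange(1, df) / df
        interior = np.quantile(distinct, probs)
    else:
        interior = np.array([])
    basis = basis_from_knots(np.array([a, b]), np.asarray(interior))
    basis._center = basis.design(x, center=False).mean(axis=0)
    return basis


def basis_from_knots(boundary_knots, interior_knots,
                     center=None) -> NaturalSplineBasis:
    """Reconstruct a natural spline basis from its knots (deterministic:
    the same knots always give the same basis columns)."""
    a, b = (float(v) for v in boundary_knots)
    interior = np.asarray(interior_knots, dtype=float)
    df = len(interior) + 1
    knots = np.r_[[a] * 4, interior, [b] * 4]
    n_b = len(interior) + 4

    # rows: second derivative of each B-spline column at the two boundaries
    C = np.empty((2, n_b))
    for j in range(n_b):
        c = np.zeros(n_b)
        c[j] = 1.0
        spl = BSpline(knots, c, 3)
        C[0, j] = spl(a, nu=2)
        C[1, j] = spl(b, nu=2)

    # null-space restriction via full QR of C^T: last n_b-2 columns of Q
    Q, _ = np.linalg.qr(C.T, mode="complete")
    H = Q[:, 2:]  # (n_b, n_b-2) = (df+3, df+1)

    # the restricted span still contains the constant; drop the first
    # column so the remaining df columns plus an intercept span the space
    transform = H[:, 1:]

    basis = NaturalSplineBasis(
        df=df,
        boundary_knots=np.array([a, b]),
        interior_knots=interior,
        _transform=transform,
        _center=np.zeros(df),
    )
    if center is not None:
        basis._center = np.asarray(center, dtype=float)
    return basis
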