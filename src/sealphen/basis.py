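"""Cubic regression-spline bases with exact curvature penalties.

A smooth term is represented by a cubic B-spline basis with knots at
quantiles of the covariate and the integrated squared second derivative
as its penalty,

    S_ij = ∫ B_i''(x) B_j''(x) dx,

computed exactly by Gauss–Legendre quadrature (B'' is piecewise linear,
so 3-point quadrature per inter-knot interval is exact). The penalty is
symmetric PSD with a 2-dimensional null space (constants and linear
functions); a *shrinkage* variant adds a small identity multiple so the
whole term can be penalized to zero, which lets smoothing-parameter
selection drop a term entirely.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import BSpline

from .errors import ModelError

logger = logging.getLogger(__name__)

#: identity multiple (relative to the scaled penalty) added by shrinkage bases
SHRINKAGE_EPS = 1e-3


def _knot_vector(x: np.ndarray, k: int) -> np.ndarray:
    """Augmented cubic knot vector with interior knots at quantiles."""
    lo, hi = float(x.min()), float(x.max())
    n_interior = k - 4
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(x), probs)
        # keep knots strictly increasing inside the span
        interior = np.clip(interior, lo + 1e-10, hi - 1e-10)
        interior = np.maximum.accumulate(interior)
    else:
        interior = np.array([])
    return np.concatenate(([lo] * 4, interior, [hi] * 4))


class CubicSplineBasis:
    """Evaluable cubic B-spline basis of dimension ``k`` on the data span.

    Attributes set at construction: ``k`` (possibly reduced), ``knots``,
    ``penalty`` (k x k curvature penalty, before any shrinkage).
    """

    def __init__(self, x, k: int = 10, shrinkage: bool = False):
        x = np.asarray(x, dtype=float)
        distinct = np.unique(x)
        if distinct.size < 4:
            raise ModelError(
                f"need >= 4 distinct covariate values, got {distinct.size}"
            )
        if distinct.size < k:
            logger.warning(
                "basis dimension reduced from %d to %d (distinct values)",
                k, distinct.size,
            )
            k = int(distinct.size)
        if k < 4:
            k = 4
        self.k = k
        self.shrinkage = shrinkage
        self.knots = _knot_vector(x, k)
        self._lo = float(x.min())
        self._hi = float(x.max())
        self.penalty = self._curvature_penalty()

    def evaluate(self, x) -> np.ndarray:
        """Basis matrix at ``x`` (values outside the span are clamped)."""
        x = np.clip(np.asarray(x, dtype=float), self._lo, self._hi)
        return BSpline.design_matrix(x, self.knots, 3).toarray()

    def _curvature_penalty(self) -> np.ndarray:
        t = self.knots
        spl = BSpline(t, np.eye(self.k), 3)
        d2 = spl.derivative(2)
        # 3-point Gauss-Legendre per breakpoint interval (exact: the
        # integrand is piecewise quadratic)
        nodes = np.array([-np.sqrt(0.6), 0.0, np.sqrt(0.6)])
        weights = np.array([5.0, 8.0, 5.0]) / 9.0
        S = np.zeros((self.k, self.k))
        breaks = np.unique(t)
        for a, b in zip(breaks[:-1], breaks[1:]):
            h = 0.5 * (b - a)
            xs = a + h * (nodes + 1.0)
            vals = d2(xs)  # (3, k)
            S += h * (vals.T * weights) @ vals
        return 0.5 * (S + S.T)


def cubic_spline_basis(x, k: int = 10,
                       shrinkage: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Basis matrix and penalty for a cubic regression spline.

    Returns ``(B, S)``: ``B`` is n x k' (k' = k, reduced with a warning
    if there are fewer distinct values), ``S`` the curvature penalty.
    Under ``shrinkage`` a small identity multiple (scaled to the
    penalty) is added so the null space is empty.
    """
    basis = CubicSplineBasis(x, k=k, shrinkage=shrinkage)
    B = basis.evaluate(x)
    S = basis.penalty.copy()
    if shrinkage:
        scale = np.trace(S) / S.shape[0]
        S = S + SHRINKAGE_EPS * max(scale, 1e-12) * np.eye(S.shape[0])
    return B, S
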