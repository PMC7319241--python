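"""Penalized cubic regression spline with GCV smoothness selection.

A compact scatterplot smoother in the generalized-additive-model idiom:
cubic B-spline basis on uniformly spaced knots spanning the data, an exact
integrated-squared-second-derivative roughness penalty, and the smoothing
parameter chosen by minimizing the generalized cross-validation score

    GCV(lam) = n * RSS(lam) / (n - edf(lam))^2 .

The penalty null space is exactly the straight lines, so noise-free affine
data are reproduced as the least-squares line for every smoothing level.
Exposed as a scikit-learn style estimator so it can be inspected, cloned
and grid-searched.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["PenalizedSplineSmoother"]

# 2-point Gauss-Legendre nodes on [0, 1]; exact for the piecewise-quadratic
# integrand B_i'' * B_j'' of a cubic spline.
_GAUSS_X = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
_GAUSS_W = np.array([0.5, 0.5])


def _knot_vector(lo: float, hi: float, n_basis: int, degree: int) -> np.ndarray:
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )


def _design(x: np.ndarray, knots: np.ndarray, degree: int, nu: int = 0) -> np.ndarray:
    n_basis = len(knots) - degree - 1
    spl = BSpline(knots, np.eye(n_basis), degree, extrapolate=True)
    if nu:
        spl = spl.derivative(nu)
    return spl(x)


def _curvature_penalty(knots: np.ndarray, degree: int) -> np.ndarray:
    """Gram matrix G_ij = integral of B_i'' B_j'' over the knot span."""
    n_basis = len(knots) - degree - 1
    G = np.zeros((n_basis, n_basis))
    breaks = np.unique(knots)
    for a, b in zip(breaks[:-1], breaks[1:]):
        xg = a + (b - a) * _GAUSS_X
        D2 = _design(xg, knots, degree, nu=2)
        G += (b - a) * (D2.T * _GAUSS_W) @ D2
    return G


class PenalizedSplineSmoother(BaseEstimator, RegressorMixin):
    """Univariate penalized cubic regression spline smoother.

    Parameters
    ----------
    n_splines : int
        Basis dimension (upper bound; reduced when the data have fewer
        distinct abscissae).
    degree : int
        Spline degree (cubic by default).
    lam : float or "gcv"
        Fixed smoothing parameter, or automatic selection by GCV over a
        log-spaced grid.
    lam_grid : tuple
        (log10 min, log10 max, count) grid searched when ``lam='gcv'``.

    Attributes
    ----------
    lam_ : float            selected smoothing parameter
    coef_ : ndarray         spline coefficients
    knots_ : ndarray        knot vector
    edf_ : float            effective degrees of freedom at ``lam_``
    gcv_score_ : float      GCV score at ``lam_`` (nan when lam is fixed)
    """

    def __init__(
        self,
        n_splines: int = 10,
        degree: int = 3,
        lam="gcv",
        lam_grid=(-8.0, 8.0, 81),
    ):
        self.n_splines = n_splines
        self.degree = degree
        self.lam = lam
        self.lam_grid = lam_grid

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("x and y must be finite")
        distinct = np.unique(x)
        if distinct.size < 2:
            raise ValueError("degenerate design: all abscissae identical")
        n_basis = int(min(self.n_splines, distinct.size))
        degree = min(self.degree, n_basis - 1)
        knots = _knot_vector(distinct[0], distinct[-1], n_basis, degree)

        B = _design(x, knots, degree)
        G = _curvature_penalty(knots, degree)
        BtB = B.T @ B
        Bty = B.T @ y
        yty = float(y @ y)
        n = len(y)

        def solve(lam):
            A = BtB + lam * G
            # ridge-free pinv fallback for rank deficiency at tiny lam
            try:
                coef = np.linalg.solve(A, Bty)
                Ainv_BtB = np.linalg.solve(A, BtB)
            except np.linalg.LinAlgError:
                Ainv = np.linalg.pinv(A)
                coef = Ainv @ Bty
                Ainv_BtB = Ainv @ BtB
            edf = float(np.trace(Ainv_BtB))
            rss = max(yty - 2.0 * coef @ Bty + coef @ BtB @ coef, 0.0)
            return coef, edf, rss

        if self.lam == "gcv":
            lo, hi, cnt = self.lam_grid
            best = None
            for lam in np.logspace(lo, hi, int(cnt)):
                coef, edf, rss = solve(lam)
                denom = n - edf
                score = np.inf if denom <= 0 else n * rss / denom**2
                if best is None or score < best[0]:
                    best = (score, lam, coef, edf)
            self.gcv_score_, self.lam_, self.coef_, self.edf_ = best
        else:
            lam = float(self.lam)
            coef, edf, _ = solve(lam)
            self.lam_, self.coef_, self.edf_, self.gcv_score_ = lam, coef, edf, np.nan
        self.knots_ = knots
        self.degree_ = degree
        return self

    def predict(self, x):
        x = np.asarray(x, dtype=float).ravel()
        return BSpline(self.knots_, self.coef_, self.degree_, extrapolate=True)(x)
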