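"""Minimal ecosystem model with a sigmoidal self-replacement feedback.

The model is the scalar ODE

    dY/dt = a - b*Y + r * f(Y),      f(Y) = Y^p / (Y^p + h^p),

where ``Y`` is an ecosystem property (e.g. dissolved oxygen in a pond),
``a`` an environmental driver that promotes ``Y``, ``b`` the decay rate of
``Y``, ``r`` the self-replacement rate, ``h`` the threshold of the shift,
and ``p`` the steepness of the feedback (its "strength").  For strong
feedback the equilibrium curve folds, producing alternative stable states
bounded by saddle-node bifurcations; ramping ``a`` up and back down then
traces a hysteresis loop.

This module provides evaluation of the vector field, fixed-step forced
simulation under a triangular driver ramp, equilibrium analysis at fixed
driver, detection of the bistable driver interval, and the critical
feedback exponent at which bistability first appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MinimalModelParams",
    "DriverRamp",
    "Trajectory",
    "EquilibriumSet",
    "self_replacement",
    "drift",
    "simulate",
    "simulate_constant",
    "equilibria",
    "bistable_interval",
    "critical_p",
]


@dataclass(frozen=True)
class MinimalModelParams:
    """Parameters of the minimal ecosystem model.

    Defaults ``b = r = h = 1`` are the standard reference configuration;
    ``p`` (dimensionless) is the feedback strength.
    """

    b: float = 1.0
    r: float = 1.0
    h: float = 1.0
    p: float = 1.0

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError(f"decay rate b must be > 0, got {self.b}")
        if not self.r >= 0:
            raise ValueError(f"self-replacement rate r must be >= 0, got {self.r}")
        if not self.h > 0:
            raise ValueError(f"threshold h must be > 0, got {self.h}")
        if not self.p >= 0:
            raise ValueError(f"feedback exponent p must be >= 0, got {self.p}")


@dataclass(frozen=True)
class DriverRamp:
    """Triangular (up-and-down) driver forcing protocol.

    The driver moves linearly from one extreme to the other over the first
    ``total_steps / 2`` unit timesteps and back over the second half.
    ``direction='up_first'`` starts at ``a_low``; ``'down_first'`` starts at
    ``a_high``.
    """

    a_low: float = 0.0
    a_high: float = 1.0
    total_steps: int = 200
    direction: Literal["up_first", "down_first"] = "up_first"

    def __post_init__(self) -> None:
        if not self.a_low < self.a_high:
            raise ValueError("require a_low < a_high")
        if self.total_steps < 2 or self.total_steps % 2:
            raise ValueError("total_steps must be even and >= 2")
        if self.direction not in ("up_first", "down_first"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def value(self, t):
        """Driver value a(t), piecewise linear, vectorized over t."""
        t = np.asarray(t, dtype=float)
        half = self.total_steps / 2.0
        frac = np.where(t <= half, t / half, (self.total_steps - t) / half)
        frac = np.clip(frac, 0.0, 1.0)
        if self.direction == "down_first":
            frac = 1.0 - frac
        return self.a_low + (self.a_high - self.a_low) * frac

    def phases(self, t):
        """Per-timestep driver-direction label ('ascending'/'descending')."""
        t = np.asarray(t, dtype=float)
        half = self.total_steps / 2.0
        first = "ascending" if self.direction == "up_first" else "descending"
        second = "descending" if self.direction == "up_first" else "ascending"
        return np.where(t <= half, first, second)


@dataclass
class Trajectory:
    """Simulated driver-response path: time, driver, state and phase labels."""

    t: np.ndarray
    a: np.ndarray
    Y: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.a) == len(self.Y) == len(self.phase) == n):
            raise ValueError("trajectory arrays must have equal length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "a": self.a, "Y": self.Y, "phase": self.phase}
        )


@dataclass(frozen=True)
class EquilibriumSet:
    """Roots of the equilibrium condition at one driver value."""

    a: float
    roots: tuple  # of (Y*, stable: bool), sorted ascending in Y*

    @property
    def stable_roots(self) -> tuple:
        return tuple(y for y, s in self.roots if s)

    @property
    def n_stable(self) -> int:
        return len(self.stable_roots)

    def lowest_stable(self) -> float:
        if not self.stable_roots:
            raise RuntimeError("no stable equilibrium found")
        return self.stable_roots[0]


def self_replacement(Y, p, h=1.0):
    """Sigmoidal feedback term f(Y) = Y^p / (Y^p + h^p), in [0, 1].

    Computed through the ratio z = Y/h for numerical stability at large p:
    f = z^p/(1+z^p) for z <= 1 and f = 1/(1+z^-p) for z > 1.  For p = 0 the
    function is defined as the constant 1/2 (the continuous limit in Y > 0).
    """
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0):
        raise ValueError("state Y must be >= 0")
    if h <= 0:
        raise ValueError("threshold h must be > 0")
    if p < 0:
        raise ValueError("exponent p must be >= 0")
    if p == 0:
        out = np.full_like(Y, 0.5)
        return out if out.ndim else float(out)
    z = Y / h
    with np.errstate(divide="ignore"):
        low = np.where(z <= 1.0, z, 1.0) ** p
        f_low = low / (1.0 + low)
        inv = np.where(z > 1.0, z, 2.0) ** (-p)
        f_high = 1.0 / (1.0 + inv)
    out = np.where(z <= 1.0, f_low, f_high)
    return out if out.ndim else float(out)


def _self_replacement_prime(Y, p, h=1.0):
    """df/dY; for p < 1 the derivative diverges at Y = 0 (returned as inf)."""
    Y = np.asarray(Y, dtype=float)
    if p == 0:
        return np.zeros_like(Y) if Y.ndim else 0.0
    z = Y / h
    f = np.asarray(self_replacement(Y, p, h))
    with np.errstate(divide="ignore", invalid="ignore"):
        # f' = (p/h) z^(p-1) (1-f)^2 / (1 in the z<=1 branch); use the
        # symmetric form f' = p f (1-f) / Y which holds for Y > 0.
        out = np.where(z > 0, p * f * (1.0 - f) / np.where(z > 0, Y, 1.0), np.nan)
    at_zero = 0.0 if p > 1 else (1.0 / h if p == 1 else np.inf)
    out = np.where(z == 0, at_zero, out)
    return out if out.ndim else float(out)


def drift(Y, a, params: MinimalModelParams):
    """Rate of change dY/dt = a - b*Y + r*f(Y)."""
    Y = np.asarray(Y, dtype=float)
    out = a - params.b * Y + params.r * self_replacement(Y, params.p, params.h)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# equilibrium analysis


def equilibria(
    a: float,
    params: MinimalModelParams,
    grid_points: int = 10_000,
    tol: float = 1e-10,
) -> EquilibriumSet:
    """All equilibria of the model at fixed driver value ``a``.

    Roots of g(Y) = a - b*Y + r*f(Y) on [0, (a+r)/b + 1] are located by a
    dense sign scan followed by bisection (scipy brentq) to |g| < tol;
    stability follows the sign of g'(Y*).
    """
    if a < 0:
        raise ValueError("driver a must be >= 0")
    b, r, h, p = params.b, params.r, params.h, params.p
    upper = (a + r) / b + 1.0
    grid = np.linspace(0.0, upper, grid_points)
    g = a - b * grid + r * np.asarray(self_replacement(grid, p, h))

    roots: list[float] = []
    if abs(g[0]) < 1e-12:
        roots.append(grid[0])
    sign = np.sign(g)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    gfun = lambda y: a - b * y + r * self_replacement(y, p, h)  # noqa: E731
    for i in crossings:
        root = brentq(gfun, grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16)
        roots.append(float(root))
    # grid points that are (numerically) exact roots without a sign change
    for i in np.nonzero(np.abs(g) < tol)[0]:
        y = float(grid[i])
        if not any(abs(y - rt) < 1e-8 for rt in roots):
            roots.append(y)
    roots = sorted(set(round(rt, 14) for rt in roots))
    if not roots:
        raise RuntimeError(f"no equilibrium found at a={a} (tolerance failure)")
    for rt in roots:
        if abs(gfun(rt)) > max(tol, 1e-9):
            raise RuntimeError(f"root refinement failed at a={a}, Y={rt}")

    out = []
    delta = 1e-7 * max(1.0, upper)
    for rt in roots:
        gprime = -b + r * _self_replacement_prime(rt, p, h)
        if gprime < -1e-8:
            stable = True
        elif gprime > 1e-8:
            stable = False
        else:
            # degenerate linearization: attracting iff the flow points
            # inward on both admissible sides (one-sided at Y = 0)
            right = gfun(rt + delta) < 0
            left = True if rt <= delta else gfun(rt - delta) > 0
            stable = bool(left and right)
        out.append((float(rt), stable))
    return EquilibriumSet(a=float(a), roots=tuple(out))


def _n_stable(a: float, params: MinimalModelParams, grid_points: int) -> int:
    return equilibria(a, params, grid_points=grid_points).n_stable


def _fold_values(
    params: MinimalModelParams,
    a_max: float,
    grid_points: int = 100_000,
) -> tuple[float, float] | None:
    """Driver values of the two saddle-node folds, or None when monostable.

    The equilibrium curve is the graph a(Y) = b*Y - r*f(Y); multiple
    equilibria exist exactly where it is non-monotone.  Critical points are
    located by a dense sign scan of a'(Y) = b - r*f'(Y) plus bisection;
    this resolves fold pairs of arbitrarily small driver separation, which
    a scan over driver values cannot.
    """
    b, r, h, p = params.b, params.r, params.h, params.p
    if p <= 1 or r == 0:
        return None  # f' is monotone: the equilibrium curve cannot fold
    upper = (a_max + r) / b + 1.0
    grid = np.linspace(1e-9, upper, grid_points)
    slope = b - r * np.asarray(_self_replacement_prime(grid, p, h))
    sign = np.sign(slope)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(crossings) < 2:
        return None
    sfun = lambda y: b - r * _self_replacement_prime(y, p, h)  # noqa: E731
    crit = [
        brentq(sfun, grid[i], grid[i + 1], xtol=1e-14) for i in crossings[:2]
    ]
    a_of = lambda y: b * y - r * self_replacement(y, p, h)  # noqa: E731
    a_hi_fold = a_of(crit[0])  # local max of a(Y): lower-branch fold
    a_lo_fold = a_of(crit[1])  # local min: upper-branch fold
    if not a_lo_fold < a_hi_fold:
        return None
    return (float(a_lo_fold), float(a_hi_fold))


def bistable_interval(
    params: MinimalModelParams,
    a_range: tuple[float, float] = (0.0, 1.0),
    grid_points: int = 100_000,
):
    """Maximal driver sub-interval of ``a_range`` with > 1 stable equilibrium.

    Returns ``(a_fold_low, a_fold_high)`` clipped to ``a_range``, or ``None``
    when the model is monostable throughout the range.
    """
    a_lo, a_hi = a_range
    folds = _fold_values(params, a_hi, grid_points)
    if folds is None:
        return None
    left, right = max(folds[0], a_lo), min(folds[1], a_hi)
    if not left < right:
        return None
    return (float(left), float(right))


def _tangency_gap(p: float) -> float:
    """max_Y f'(Y) - 1 for b = r = h = 1, via the closed-form maximizer.

    The maximizer of f'(Y) satisfies Y^p = (p-1)/(p+1), giving
    max f' = ((p-1)/(p+1))^((p-1)/p) * (p+1)^2 / (4p).  Bistability (for
    b = r = 1) requires max f' > 1.
    """
    if p <= 1:
        return 0.0 if p == 1 else -1.0
    ratio = (p - 1.0) / (p + 1.0)
    return ratio ** ((p - 1.0) / p) * (p + 1.0) ** 2 / (4.0 * p) - 1.0


def critical_p(
    params: MinimalModelParams | None = None,
    method: Literal["auto", "closed_form", "scan"] = "auto",
    scan_tol: float = 1e-4,
) -> float:
    """Feedback exponent at which alternative stable states first appear.

    For the reference case b = r = h = 1 the closed-form tangency condition
    max_Y f'(Y) = 1 is solved on (2, 10); the root lies in (3, 4).  For
    general parameters (or ``method='scan'``) the transition is found by
    bisection on the emptiness of :func:`bistable_interval`.
    """
    if params is None:
        params = MinimalModelParams()
    reference = params.b == params.r == params.h == 1.0
    if method == "auto":
        method = "closed_form" if reference else "scan"
    if method == "closed_form":
        if not reference:
            raise ValueError("closed form requires b = r = h = 1")
        return float(brentq(_tangency_gap, 2.0, 10.0, xtol=1e-12))

    def is_bistable(p: float) -> bool:
        trial = MinimalModelParams(b=params.b, r=params.r, h=params.h, p=p)
        return bistable_interval(trial) is not None

    lo, hi = 0.0, 10.0
    if is_bistable(lo) or not is_bistable(hi):
        raise RuntimeError("bistability transition not bracketed in p range [0, 10]")
    while hi - lo > scan_tol:
        mid = 0.5 * (lo + hi)
        if is_bistable(mid):
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# forced simulation


def _integrate_ramp(
    p_values: np.ndarray,
    ramp: DriverRamp,
    base: MinimalModelParams,
    Y0: np.ndarray,
    substeps: int = 10,
) -> np.ndarray:
    """RK4 integration of the ramped model for a vector of p values at once.

    One output row per unit timestep (t = 0 .. total_steps); ``substeps``
    fixed RK4 steps per unit time; a(t) is evaluated continuously
    (piecewise linear).  Returns array of shape (total_steps + 1, len(p)).
    """
    p_values = np.atleast_1d(np.asarray(p_values, dtype=float))
    b, r, h = base.b, base.r, base.h
    T = ramp.total_steps
    dt = 1.0 / substeps
    Y = np.array(Y0, dtype=float, copy=True)
    if Y.shape != p_values.shape:
        raise ValueError("Y0 must match p_values in shape")
    out = np.empty((T + 1, len(p_values)))
    out[0] = Y

    # driver values at RK nodes, precomputed for the whole run
    sub_t = np.arange(T * substeps) * dt
    a_node = np.asarray(ramp.value(sub_t))
    a_half = np.asarray(ramp.value(sub_t + 0.5 * dt))
    a_next = np.asarray(ramp.value(sub_t + dt))

    def g(Y, a):
        # z**0 == 1 gives f = 1/2 for p = 0, matching the continuity choice
        zp = (Y / h) ** p_values
        return a - b * Y + r * (zp / (1.0 + zp))

    dt6 = dt / 6.0
    i = 0
    for step in range(T):
        for _ in range(substeps):
            k1 = g(Y, a_node[i])
            k2 = g(np.maximum(Y + 0.5 * dt * k1, 0.0), a_half[i])
            k3 = g(np.maximum(Y + 0.5 * dt * k2, 0.0), a_half[i])
            k4 = g(np.maximum(Y + dt * k3, 0.0), a_next[i])
            Y = np.maximum(Y + dt6 * (k1 + 2.0 * (k2 + k3) + k4), 0.0)
            i += 1
        if not np.all(np.isfinite(Y)):
            raise RuntimeError(f"integration diverged at timestep {step + 1}")
        out[step + 1] = Y
    return out


def simulate_constant(
    params: MinimalModelParams,
    a: float,
    Y0: float,
    total_steps: int,
    substeps: int = 10,
) -> Trajectory:
    """Relaxation run at fixed driver; converges to a stable equilibrium."""
    if a < 0:
        raise ValueError("driver a must be >= 0")
    if Y0 < 0:
        raise ValueError("Y0 must be >= 0")

    class _Const:
        @staticmethod
        def value(t):
            t = np.asarray(t, dtype=float)
            return np.full_like(t, float(a)) if t.ndim else float(a)

    const = _Const()
    const.total_steps = total_steps
    Ymat = _integrate_ramp(
        np.array([params.p]), const, params, np.array([float(Y0)]), substeps=substeps
    )
    t = np.arange(total_steps + 1, dtype=float)
    return Trajectory(
        t=t,
        a=np.full_like(t, float(a)),
        Y=Ymat[:, 0],
        phase=np.full(t.shape, "ascending", dtype=object),
    )


def simulate(
    params: MinimalModelParams,
    ramp: DriverRamp,
    Y0: float | str = "auto",
    substeps: int = 10,
) -> Trajectory:
    """Simulate the model under the triangular ramp, one output per timestep.

    ``Y0='auto'`` starts from the lowest stable equilibrium at the initial
    driver value, so an up-first sweep starts on the lower branch and a
    down-first sweep on the branch stable at ``a_high``.
    """
    a0 = float(ramp.value(0.0))
    if Y0 == "auto":
        y0 = equilibria(a0, params).lowest_stable()
    else:
        y0 = float(Y0)
        if y0 < 0:
            raise ValueError("Y0 must be >= 0")
    Ymat = _integrate_ramp(
        np.array([params.p]), ramp, params, np.array([y0]), substeps=substeps
    )
    t = np.arange(ramp.total_steps + 1, dtype=float)
    return Trajectory(t=t, a=ramp.value(t), Y=Ymat[:, 0], phase=ramp.phases(t))
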