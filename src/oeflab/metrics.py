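"""Nonlinearity and hysteresis of a state variable against a ramped driver.

Two scalar response statistics for one driver-response path:

* absolute nonlinearity: the root-mean-square difference between the fitted
  values of an ordinary least-squares line and of a penalized-spline
  smoother, computed per forcing phase on unstandardized data;
* hysteresis: the mean absolute difference between the ascending-phase and
  descending-phase states paired at equal driver values.

Both are in the units of the state variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smoothing import PenalizedSplineSmoother

__all__ = [
    "DriverResponsePath",
    "MetricResult",
    "fit_line",
    "fit_smooth",
    "nonlinearity",
    "pair_updown",
    "hysteresis",
    "compute_metrics",
    "path_from_trajectory",
    "metrics_table",
    "paths_from_table",
]

_PHASES = ("ascending", "descending")


@dataclass
class DriverResponsePath:
    """One replicate's state-vs-driver path with per-point phase labels."""

    E: np.ndarray
    Y: np.ndarray
    phase: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.E) == len(self.Y) == len(self.phase)):
            raise ValueError("E, Y and phase must have equal length")
        bad = set(self.phase) - set(_PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")

    def split(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.phase == phase
        return self.E[m], self.Y[m]


@dataclass(frozen=True)
class MetricResult:
    """Nonlinearity per phase plus hysteresis for one path/variable."""

    id: str
    nonlinearity_up: float
    nonlinearity_down: float
    hysteresis: float
    n_pairs: int


def fit_line(E, Y) -> np.ndarray:
    """Fitted values of the ordinary least-squares straight line at each E."""
    E = np.asarray(E, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.unique(E).size < 2:
        raise ValueError("degenerate design: need >= 2 distinct driver values")
    X = np.column_stack([np.ones_like(E), E])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return X @ beta


def fit_smooth(E, Y, basis_dim: int = 10, lam="gcv") -> np.ndarray:
    """Fitted values of the penalized cubic regression spline at each E.

    Smoothness is selected by generalized cross-validation by default; the
    basis dimension shrinks automatically when fewer distinct driver values
    are available.
    """
    sm = PenalizedSplineSmoother(n_splines=basis_dim, lam=lam)
    sm.fit(E, Y)
    return sm.predict(np.asarray(E, dtype=float))


def nonlinearity(E, Y, basis_dim: int = 10) -> float:
    """RMS difference between smoother and line fits (state units, >= 0)."""
    line = fit_line(E, Y)
    smooth = fit_smooth(E, Y, basis_dim=basis_dim)
    return float(np.sqrt(np.mean((smooth - line) ** 2)))


def _collapse_duplicates(E: np.ndarray, Y: np.ndarray, decimals: int = 9):
    """Average Y over repeated driver levels (rounded for float matching)."""
    key = np.round(E, decimals)
    df = pd.DataFrame({"E": key, "Y": Y}).groupby("E", sort=True).mean()
    return df.index.to_numpy(), df["Y"].to_numpy()


def pair_updown(path: DriverResponsePath, decimals: int = 9) -> pd.DataFrame:
    """Match ascending and descending observations at common driver levels.

    Within-phase repeats of a driver level are averaged first.  Exact
    matching is tried first, excluding the two extreme levels of the full
    path (each extreme is visited in one direction only, or bridges the
    turning point).  When no interior exact matches exist (asymmetric
    schedules), the descending path is linearly interpolated onto the
    ascending levels strictly interior to its range.

    Returns a frame with columns E, Y_up, Y_down.
    """
    E_up, Y_up = path.split("ascending")
    E_dn, Y_dn = path.split("descending")
    if len(E_up) == 0 or len(E_dn) == 0:
        raise ValueError("both phases must be present to pair")
    E_up, Y_up = _collapse_duplicates(E_up, Y_up, decimals)
    E_dn, Y_dn = _collapse_duplicates(E_dn, Y_dn, decimals)

    lo = np.round(min(E_up.min(), E_dn.min()), decimals)
    hi = np.round(max(E_up.max(), E_dn.max()), decimals)
    common = np.intersect1d(E_up, E_dn)
    common = common[(common != lo) & (common != hi)]
    if common.size:
        up_map = dict(zip(E_up, Y_up))
        dn_map = dict(zip(E_dn, Y_dn))
        return pd.DataFrame(
            {
                "E": common,
                "Y_up": [up_map[e] for e in common],
                "Y_down": [dn_map[e] for e in common],
            }
        )
    # interpolation fallback: descending path sampled at ascending levels
    inner = E_up[(E_up > E_dn.min()) & (E_up < E_dn.max())]
    if inner.size == 0:
        raise ValueError("no driver levels could be paired between phases")
    order = np.argsort(E_dn)
    y_interp = np.interp(inner, E_dn[order], Y_dn[order])
    up_map = dict(zip(E_up, Y_up))
    return pd.DataFrame(
        {"E": inner, "Y_up": [up_map[e] for e in inner], "Y_down": y_interp}
    )


def hysteresis(path: DriverResponsePath, decimals: int = 9) -> float:
    """Mean absolute up-down state difference over paired driver levels."""
    pairs = pair_updown(path, decimals=decimals)
    return float(np.mean(np.abs(pairs["Y_up"] - pairs["Y_down"])))


def compute_metrics(path: DriverResponsePath, basis_dim: int = 10) -> MetricResult:
    """Nonlinearity of each phase and hysteresis of the full path."""
    E_up, Y_up = path.split("ascending")
    E_dn, Y_dn = path.split("descending")
    for E_phase in (E_up, E_dn):
        if len(E_phase) < 4:
            raise ValueError("each phase needs >= 4 points for line + smoother fits")
    pairs = pair_updown(path)
    return MetricResult(
        id=path.id,
        nonlinearity_up=nonlinearity(E_up, Y_up, basis_dim=basis_dim),
        nonlinearity_down=nonlinearity(E_dn, Y_dn, basis_dim=basis_dim),
        hysteresis=float(np.mean(np.abs(pairs["Y_up"] - pairs["Y_down"]))),
        n_pairs=len(pairs),
    )


def path_from_trajectory(traj, id: str = "") -> DriverResponsePath:
    """Adapt a model :class:`~oeflab.model.Trajectory` to a response path."""
    return DriverResponsePath(E=traj.a, Y=traj.Y, phase=traj.phase, id=id)


def metrics_table(paths, basis_dim: int = 10) -> pd.DataFrame:
    """Metrics for a collection of paths as a tidy frame."""
    rows = [compute_metrics(p, basis_dim=basis_dim).__dict__ for p in paths]
    return pd.DataFrame(rows)


def paths_from_table(
    table: pd.DataFrame, variable: str, split_day: float = 33.0
) -> list[DriverResponsePath]:
    """Per-microcosm temperature-response paths from an experiment table.

    The forcing phase is split at the schedule midpoint: sampling days up
    to ``split_day`` are the ascending (warming) phase, later days the
    descending phase, with the peak-temperature plateau shared between
    them.
    """
    out = []
    for mid, d in table.groupby("microcosm_id", sort=False):
        d = d.sort_values("day")
        phase = np.where(d["day"] <= split_day, "ascending", "descending")
        out.append(
            DriverResponsePath(
                E=d["temperature"].to_numpy(),
                Y=d[variable].to_numpy(),
                phase=phase,
                id=str(mid),
            )
        )
    return out
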