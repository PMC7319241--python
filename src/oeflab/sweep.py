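"""Feedback-strength x ramp-rate sweep of the minimal ecosystem model.

For every combination of feedback exponent p, ramp length (fast vs slow)
and forcing direction, the model is simulated under the triangular driver
protocol, the path is split into ascending/descending phases, and the
nonlinearity and hysteresis statistics are computed, together with the
maximum number of coexisting stable equilibria over the swept driver range.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .metrics import compute_metrics, path_from_trajectory
from .model import (
    DriverRamp,
    MinimalModelParams,
    Trajectory,
    _integrate_ramp,
    bistable_interval,
    equilibria,
)

__all__ = ["SweepRecord", "run_sweep", "classify_regime", "max_stable_states"]


@dataclass(frozen=True)
class SweepRecord:
    """One sweep cell: (p, ramp length, direction) and its response metrics."""

    p: float
    total_steps: int
    direction: str
    nonlinearity_up: float
    nonlinearity_down: float
    hysteresis: float
    max_stable_states: int


def max_stable_states(
    params: MinimalModelParams,
    a_range: tuple[float, float] = (0.0, 1.0),
    n_a: int = 101,
) -> int:
    """Maximum stable-equilibrium count over the driver range ``a_range``.

    Evaluated on a uniform driver grid plus, when the model has a fold pair,
    the midpoint of the bistable interval — so windows narrower than the
    grid spacing are still counted.
    """
    probes = list(np.linspace(*a_range, n_a))
    interval = bistable_interval(params, a_range)
    if interval is not None:
        probes.append(0.5 * (interval[0] + interval[1]))
    return max(equilibria(a, params).n_stable for a in probes)


def classify_regime(
    p: float,
    params: MinimalModelParams | None = None,
    a_range: tuple[float, float] = (0.0, 1.0),
) -> str:
    """'bistable' if alternative stable states occur in ``a_range``, else 'monostable'."""
    base = params or MinimalModelParams()
    trial = MinimalModelParams(b=base.b, r=base.r, h=base.h, p=p)
    return "bistable" if bistable_interval(trial, a_range) is not None else "monostable"


def _sweep_one_rate(
    p_grid: np.ndarray,
    ramp: DriverRamp,
    base: MinimalModelParams,
    substeps: int,
    basis_dim: int,
    stable_counts: dict,
) -> list[SweepRecord]:
    # all p values integrated jointly: the scalar ODEs share the driver
    a0 = float(ramp.value(0.0))
    Y0 = np.array(
        [
            equilibria(
                a0, MinimalModelParams(b=base.b, r=base.r, h=base.h, p=p)
            ).lowest_stable()
            for p in p_grid
        ]
    )
    Ymat = _integrate_ramp(p_grid, ramp, base, Y0, substeps=substeps)
    t = np.arange(ramp.total_steps + 1, dtype=float)
    a = ramp.value(t)
    phase = ramp.phases(t)
    records = []
    for j, p in enumerate(p_grid):
        traj = Trajectory(t=t, a=a, Y=Ymat[:, j], phase=phase)
        try:
            m = compute_metrics(
                path_from_trajectory(traj, id=f"p={p:g}"), basis_dim=basis_dim
            )
        except (ValueError, np.linalg.LinAlgError) as err:  # record and skip
            records.append(
                SweepRecord(
                    p=float(p),
                    total_steps=ramp.total_steps,
                    direction=ramp.direction,
                    nonlinearity_up=np.nan,
                    nonlinearity_down=np.nan,
                    hysteresis=np.nan,
                    max_stable_states=stable_counts[float(p)],
                )
            )
            continue
        records.append(
            SweepRecord(
                p=float(p),
                total_steps=ramp.total_steps,
                direction=ramp.direction,
                nonlinearity_up=m.nonlinearity_up,
                nonlinearity_down=m.nonlinearity_down,
                hysteresis=m.hysteresis,
                max_stable_states=stable_counts[float(p)],
            )
        )
    return records


def run_sweep(
    p_grid: Sequence[float] | None = None,
    step_grid: Sequence[int] = (200, 20_000),
    directions: Sequence[str] = ("up_first",),
    params: MinimalModelParams | None = None,
    a_low: float = 0.0,
    a_high: float = 1.0,
    substeps: int = 10,
    basis_dim: int = 10,
) -> pd.DataFrame:
    """Run the full p x rate x direction sweep; one row per combination.

    Default grids: p from 0 to 10 in steps of 0.5, ramp lengths 200 (fast)
    and 20 000 (slow) unit timesteps.  Results are independent of the
    evaluation order.
    """
    base = params or MinimalModelParams()
    if p_grid is None:
        p_grid = np.arange(0.0, 10.0 + 1e-9, 0.5)
    p_grid = np.asarray(sorted(p_grid), dtype=float)
    if p_grid.min() < 0 or p_grid.max() > 10:
        raise ValueError("p_grid must lie within [0, 10]")

    stable_counts = {
        float(p): max_stable_states(
            MinimalModelParams(b=base.b, r=base.r, h=base.h, p=p),
            (a_low, a_high),
        )
        for p in p_grid
    }
    records: list[SweepRecord] = []
    for steps in step_grid:
        for direction in directions:
            ramp = DriverRamp(
                a_low=a_low, a_high=a_high, total_steps=int(steps), direction=direction
            )
            records.extend(
                _sweep_one_rate(
                    p_grid, ramp, base, substeps, basis_dim, stable_counts
                )
            )
    return pd.DataFrame([asdict(rec) for rec in records])
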