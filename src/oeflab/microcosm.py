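"""Seeded synthetic microcosm experiment generator.

Emulates a 67-day aquatic microcosm experiment: a tri-trophic community
(two bacteria-feeding ciliate prey species and one predatory ciliate, on a
bacterial resource) in sealed jars whose gas exchange with the atmosphere is
manipulated in five treatments, while temperature is ramped 15 -> 25 -> 15 C
in 0.7 C steps every two days with a one-week plateau.  Oxygen lives in two
compartments (liquid and headspace) on the optode sensor scale where
equilibrium with the atmosphere reads 21 %O2; community respiration drains
liquid oxygen, the headspace resupplies the liquid, and the treatment sets
how fast the headspace itself is refreshed (continuously for the open
treatment, by discrete air additions every second day for the pulsed
treatments, essentially not at all for the closed one).

Low dissolved oxygen limits predation, which is what couples community fate
to the gas-exchange treatment: with free exchange the predator drives its
prey extinct and then starves (functional extinction; oxygen recovers),
while under weak exchange the oxygen drawdown shelters prey so that the
predator-prey system can persist and keep consuming oxygen (the low-DO
regime).  Multiplicative environmental noise makes replicates diverge
between these two regimes.  The generator records the realized regime of
every microcosm, derived from the latent (noise-free-observation) oxygen
trajectory, as hidden ground truth for validating regime-detection methods.

All biological parameter values are defaults chosen to produce this
qualitative phenomenology; they are not estimates of any real system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureProtocol",
    "GasExchangeTreatment",
    "MicrocosmState",
    "MicrocosmConfig",
    "TREATMENT_ORDER",
    "default_treatments",
    "temperature_at",
    "biovolume",
    "step_dynamics",
    "service_event",
    "observe",
    "generate_experiment",
]

# weak -> strong feedback (decreasing gas exchange)
TREATMENT_ORDER = ("open", "add200", "add100", "add50", "closed")


@dataclass(frozen=True)
class TemperatureProtocol:
    """Stepped triangular temperature forcing with a plateau at the peak."""

    t_start: float = 15.0
    t_peak: float = 25.0
    step: float = 0.7
    step_interval: float = 2.0
    ramp_days: float = 30.0
    hold_days: float = 7.0

    @property
    def total_days(self) -> float:
        return 2 * self.ramp_days + self.hold_days


def temperature_at(day: float, protocol: TemperatureProtocol | None = None) -> float:
    """Temperature (C) on a given day, piecewise constant between steps.

    Ascends from ``t_start`` by ``step`` every ``step_interval`` days, is
    capped at ``t_peak`` through the plateau, and descends symmetrically
    (the profile is the mirror image of the ascent about the midpoint), so
    the final sampled day is back at ``t_start``.
    """
    prot = protocol or TemperatureProtocol()
    if day < 0:
        raise ValueError("day must be >= 0")
    mirrored = min(day, prot.total_days - day)
    if mirrored < 0:
        mirrored = 0.0
    n_steps = math.floor(mirrored / prot.step_interval)
    return min(prot.t_start + prot.step * n_steps, prot.t_peak)


@dataclass(frozen=True)
class GasExchangeTreatment:
    """Headspace-atmosphere exchange: continuous rate plus service pulses.

    ``k_atm`` (per day) is the continuous relaxation rate of the headspace
    toward the atmospheric 21 %O2 (large for the open sponge-stoppered
    treatment, a small leak otherwise); ``pulse_fraction`` is the fraction
    of the headspace refreshed toward atmospheric at each 2-day air
    addition, which bubbles through the liquid and also refreshes a
    fraction ``pulse_liquid_ratio * pulse_fraction`` of the liquid.
    """

    label: str
    k_atm: float
    pulse_fraction: float = 0.0
    pulse_liquid_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.k_atm < 0 or not 0 <= self.pulse_fraction <= 1:
            raise ValueError("invalid gas-exchange parameters")


def default_treatments(k_leak: float = 0.06, k_open: float = 30.0) -> dict:
    """The five gas-exchange levels, ordered weak -> strong feedback.

    Air additions of 200/100/50 ml map to headspace refresh fractions
    0.8/0.5/0.3 (the headspace is roughly 150 ml).  Even the closed jar
    keeps a small leak: no treatment is perfectly sealed.
    """
    return {
        "open": GasExchangeTreatment("open", k_atm=k_open),
        "add200": GasExchangeTreatment("add200", k_atm=k_leak, pulse_fraction=0.8),
        "add100": GasExchangeTreatment("add100", k_atm=k_leak, pulse_fraction=0.5),
        "add50": GasExchangeTreatment("add50", k_atm=k_leak, pulse_fraction=0.3),
        "closed": GasExchangeTreatment("closed", k_atm=k_leak),
    }


@dataclass
class MicrocosmState:
    """Latent state of one microcosm (densities per ml, %O2 sensor scale)."""

    O_liq: float = 10.0
    O_head: float = 21.0
    B: float = 1.0e6
    N1: float = 400.0
    N2: float = 600.0
    P: float = 10.0
    day: float = 0.0
    cyst_pool: bool = False  # predator encysted, may re-emerge

    def clip(self) -> None:
        self.O_liq = min(max(self.O_liq, 0.0), 22.0)
        self.O_head = min(max(self.O_head, 0.0), 22.0)
        self.B = max(self.B, 0.0)
        self.N1 = max(self.N1, 0.0)
        self.N2 = max(self.N2, 0.0)
        self.P = max(self.P, 0.0)


def _gauss(T: float, opt: float, width: float) -> float:
    return math.exp(-0.5 * ((T - opt) / width) ** 2)


@dataclass
class MicrocosmConfig:
    """Biology, physics and noise defaults for the synthetic experiment."""

    # bacteria (cells/ml): logistic resupply from the slow-release nutrients
    r_B: float = 2.0
    K_B: float = 5.0e6
    # prey (ind/ml): bacterivory with Gaussian thermal performance
    r_N: float = 1.1
    H_B: float = 2.0e6
    graze: float = 1.0e3  # bacteria cells removed per prey per day at saturation
    m_N: float = 0.08
    K_N: float = 1500.0  # prey carrying capacity (ind/ml, joint)
    T_opt_N1: float = 24.0
    T_opt_N2: float = 26.0
    T_width_N: float = 6.0
    # predator (ind/ml): saturating predation, limited by dissolved oxygen
    attack: float = 42.0  # prey eaten per predator per day at saturation
    H_N: float = 300.0
    eps: float = 0.03  # predators produced per prey eaten
    m_P: float = 0.11
    T_opt_P: float = 19.0
    T_width_P: float = 6.0
    K_O: float = 20.0  # %O2 at which predation is half its maximal rate (Hill-2)
    # oxygen (sensor %O2): respiration drain and exchange
    resp_B: float = 4.0e-8  # %O2 per day per cell/ml at 15 C
    resp_N: float = 8.0e-3
    resp_P: float = 2.0e-2
    Q10: float = 2.0
    K_resp: float = 1.0  # Michaelis constant of respiration in O_liq
    k_LH: float = 4.0  # liquid <-> headspace relaxation (per day)
    head_cap_ratio: float = 0.3  # liquid-to-headspace oxygen capacity ratio
    O_atm: float = 21.0
    # stochasticity and detection limits
    sigma_env: float = 0.15  # environmental noise on biotic rates (per sqrt day)
    sigma_obs: float = 0.08  # lognormal observation noise on densities
    floor_B: float = 1.0e3
    floor_N: float = 1.0
    floor_P: float = 0.2
    cyst_trigger: float = 200.0  # prey/ml at which cysts re-emerge
    cyst_density: float = 1.0
    dt: float = 0.05
    # initial conditions (approximately 10 %DO, 1e6 bacteria, 1e3 prey, 10 predators)
    O_liq0: float = 10.0
    O_head0: float = 21.0
    B0: float = 1.0e6
    N10: float = 400.0
    N20: float = 600.0
    P0: float = 10.0
    # morphology (um), per species: mean/sd of width and length draws
    morph: dict = field(
        default_factory=lambda: {
            "N1": (25.0, 2.5, 50.0, 5.0),
            "N2": (18.0, 2.0, 38.0, 4.0),
            "P": (40.0, 4.0, 120.0, 12.0),
        }
    )
    n_morph: int = 10  # individuals measured per species per sample
    # hidden regime ground truth: sustained hypoxia of the latent DO series
    regime_o_threshold: float = 8.0
    regime_min_day: float = 10.0
    protocol: TemperatureProtocol = field(default_factory=TemperatureProtocol)
    n_replicates: int = 6

    def validate(self) -> None:
        bad = [
            k
            for k in (
                "r_B r_N graze attack eps K_B H_B H_N K_O K_resp k_LH "
                "Q10 head_cap_ratio dt n_morph".split()
            )
            if getattr(self, k) <= 0
        ]
        bad += [
            k
            for k in "m_N m_P sigma_env sigma_obs floor_B floor_N floor_P".split()
            if getattr(self, k) < 0
        ]
        if self.dt > 0.1:
            bad.append("dt")
        if bad:
            raise ValueError(f"invalid configuration values: {sorted(set(bad))}")


def biovolume(width: float, length: float) -> float:
    """Ellipsoid biovolume (um^3) from width and length (um)."""
    w = np.asarray(width, dtype=float)
    l = np.asarray(length, dtype=float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise ValueError("width and length must be > 0")
    out = (4.0 / 3.0) * np.pi * (w / 2.0) ** 2 * (l / 2.0)
    return out if out.ndim else float(out)


def step_dynamics(
    state: MicrocosmState,
    treatment: GasExchangeTreatment,
    temperature: float,
    dt: float,
    rng: np.random.Generator | None,
    config: MicrocosmConfig | None = None,
) -> MicrocosmState:
    """One Euler-Maruyama update of the community-oxygen dynamics.

    ``rng=None`` disables the environmental noise (deterministic update).
    """
    c = config or MicrocosmConfig()
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 day")
    s = state
    T = temperature

    ntot = s.N1 + s.N2
    f_O = s.O_liq**2 / (s.O_liq**2 + c.K_O**2)
    food = s.B / (s.B + c.H_B)
    q10 = c.Q10 ** ((T - 15.0) / 10.0)

    # per-capita rates
    growth_N1 = c.r_N * _gauss(T, c.T_opt_N1, c.T_width_N) * food
    growth_N2 = c.r_N * _gauss(T, c.T_opt_N2, c.T_width_N) * food
    pred_rate = (
        c.attack * f_O * _gauss(T, c.T_opt_P, c.T_width_P) * ntot / (ntot + c.H_N)
    )
    pred_per_prey = 0.0 if ntot == 0 else pred_rate * s.P / ntot

    if rng is not None:
        sig = c.sigma_env * math.sqrt(dt)
        eta = rng.normal(0.0, 1.0, 4)
    else:
        sig = 0.0
        eta = np.zeros(4)

    dB = (
        c.r_B * q10 * s.B * (1.0 - s.B / c.K_B)
        - c.graze * (growth_N1 * s.N1 + growth_N2 * s.N2) / c.r_N
    )
    crowd = max(1.0 - ntot / c.K_N, 0.0)
    dN1 = (growth_N1 * crowd - c.m_N - pred_per_prey) * s.N1
    dN2 = (growth_N2 * crowd - c.m_N - pred_per_prey) * s.N2
    dP = (c.eps * pred_rate - c.m_P) * s.P

    resp = (
        (c.resp_B * s.B + c.resp_N * ntot + c.resp_P * s.P)
        * q10
        * s.O_liq
        / (s.O_liq + c.K_resp)
    )
    flux = c.k_LH * (s.O_head - s.O_liq)
    dO_liq = flux - resp
    dO_head = -c.head_cap_ratio * flux + treatment.k_atm * (c.O_atm - s.O_head)

    nxt = MicrocosmState(
        O_liq=s.O_liq + dt * dO_liq,
        O_head=s.O_head + dt * dO_head,
        B=max(s.B + dt * dB, 0.0) * math.exp(sig * eta[0] - 0.5 * sig**2),
        N1=max(s.N1 + dt * dN1, 0.0) * math.exp(sig * eta[1] - 0.5 * sig**2),
        N2=max(s.N2 + dt * dN2, 0.0) * math.exp(sig * eta[2] - 0.5 * sig**2),
        P=max(s.P + dt * dP, 0.0) * math.exp(sig * eta[3] - 0.5 * sig**2),
        day=s.day + dt,
        cyst_pool=s.cyst_pool,
    )
    # extinction floors: absorbing for bacteria and prey; the predator
    # leaves a cyst pool and re-emerges when prey recover
    if 0.0 < nxt.B < c.floor_B:
        nxt.B = 0.0
    if 0.0 < nxt.N1 < c.floor_N:
        nxt.N1 = 0.0
    if 0.0 < nxt.N2 < c.floor_N:
        nxt.N2 = 0.0
    if 0.0 < nxt.P < c.floor_P:
        nxt.P = 0.0
        nxt.cyst_pool = True
    if nxt.cyst_pool and nxt.P == 0.0 and (nxt.N1 + nxt.N2) > c.cyst_trigger:
        nxt.P = c.cyst_density
        nxt.cyst_pool = False
    nxt.clip()
    if not all(
        np.isfinite(v) for v in (nxt.O_liq, nxt.O_head, nxt.B, nxt.N1, nxt.N2, nxt.P)
    ):
        raise RuntimeError(f"nonfinite state at day {s.day:.2f}")
    return nxt


def service_event(
    state: MicrocosmState,
    treatment: GasExchangeTreatment,
    config: MicrocosmConfig | None = None,
) -> MicrocosmState:
    """Discrete air addition: pulsed gas refresh toward atmospheric.

    The added air displaces a treatment-specific fraction of the headspace
    and, because it bubbles through the liquid, also refreshes a smaller
    fraction of the liquid directly.
    """
    c = config or MicrocosmConfig()
    pf = treatment.pulse_fraction
    out = MicrocosmState(**{**asdict(state)})
    out.O_head = state.O_head + pf * (c.O_atm - state.O_head)
    out.O_liq = state.O_liq + treatment.pulse_liquid_ratio * pf * (
        c.O_atm - state.O_liq
    )
    out.clip()
    return out


def observe(
    state: MicrocosmState,
    rng: np.random.Generator | None,
    config: MicrocosmConfig | None = None,
) -> dict:
    """One sampling event: noisy densities, morphology draws, total biomass.

    Densities get lognormal observation noise (``rng=None`` disables it);
    per-species morphology (width, length) is drawn for ``n_morph``
    individuals and total biomass is the sum over ciliate species of
    density times the mean per-individual biovolume of that sample's draws.
    """
    c = config or MicrocosmConfig()

    def noisy(x: float) -> float:
        if rng is None or c.sigma_obs == 0 or x == 0:
            return x
        return x * math.exp(rng.normal(0.0, c.sigma_obs) - 0.5 * c.sigma_obs**2)

    row = {
        "O_liq": state.O_liq,
        "O_head": state.O_head,
        "bacteria_per_ml": noisy(state.B),
        "prey1_per_ml": noisy(state.N1),
        "prey2_per_ml": noisy(state.N2),
        "predator_per_ml": noisy(state.P),
    }
    total = 0.0
    dens = {
        "N1": row["prey1_per_ml"],
        "N2": row["prey2_per_ml"],
        "P": row["predator_per_ml"],
    }
    for sp, (wm, ws, lm, ls) in c.morph.items():
        if rng is None:
            w = np.full(c.n_morph, wm)
            l = np.full(c.n_morph, lm)
        else:
            w = np.maximum(rng.normal(wm, ws, c.n_morph), 1.0)
            l = np.maximum(rng.normal(lm, ls, c.n_morph), 1.0)
        vol = float(np.mean(biovolume(w, l)))
        key = {"N1": "prey1", "N2": "prey2", "P": "predator"}[sp]
        row[f"width_{key}"] = float(np.mean(w))
        row[f"length_{key}"] = float(np.mean(l))
        row[f"biovolume_{key}"] = vol
        total += dens[sp] * vol
    row["total_biomass"] = total
    return row


def _run_microcosm(
    treatment: GasExchangeTreatment,
    rng: np.random.Generator | None,
    config: MicrocosmConfig,
) -> tuple[list[dict], dict]:
    """Simulate one microcosm; returns sample rows and latent ground truth."""
    c = config
    prot = c.protocol
    state = MicrocosmState(
        O_liq=c.O_liq0, O_head=c.O_head0, B=c.B0, N1=c.N10, N2=c.N20, P=c.P0
    )
    n_days = int(prot.total_days)
    sample_days = list(range(0, n_days, 2))
    steps_per_day = int(round(1.0 / c.dt))
    rows = []
    latent_o_min = np.inf
    for day in range(n_days + 1):
        if day in sample_days:
            if day >= c.regime_min_day:
                latent_o_min = min(latent_o_min, state.O_liq)
            row = {"day": day, "temperature": temperature_at(day, prot)}
            row.update(observe(state, rng, c))
            rows.append(row)
        if day == n_days:
            break
        if day > 0 and day % 2 == 0 and treatment.pulse_fraction > 0:
            state = service_event(state, treatment, c)
        T = temperature_at(day + 0.5, prot)  # within-day temperature
        for _ in range(steps_per_day):
            state = step_dynamics(state, treatment, T, c.dt, rng, c)
    truth = {
        "regime": "low_do" if latent_o_min < c.regime_o_threshold else "recovery",
        "persisted": bool((state.N1 + state.N2) > 0.0),
    }
    return rows, truth


def generate_experiment(
    config: MicrocosmConfig | None = None,
    seed: int = 0,
    treatments: dict | None = None,
) -> pd.DataFrame:
    """Generate the full 30-microcosm experiment table (long format).

    Five gas-exchange treatments x ``n_replicates`` replicates, sampled
    every second day.  Deterministic given ``seed``; every microcosm uses
    an independent RNG substream keyed by (seed, treatment, replicate), so
    adding replicates never perturbs existing ones.  The hidden
    ground-truth regime of each microcosm is recorded in the ``regime``
    and ``persisted`` columns.
    """
    c = config or MicrocosmConfig()
    c.validate()
    trts = treatments or default_treatments()
    frames = []
    for ti, label in enumerate(TREATMENT_ORDER):
        trt = trts[label]
        for rep in range(c.n_replicates):
            rng = (
                None
                if c.sigma_env == 0 and c.sigma_obs == 0
                else np.random.default_rng([int(seed), ti, rep])
            )
            rows, truth = _run_microcosm(trt, rng, c)
            df = pd.DataFrame(rows)
            df.insert(0, "microcosm_id", f"{label}_r{rep + 1}")
            df.insert(1, "treatment", label)
            df.insert(2, "replicate", rep + 1)
            df["regime"] = truth["regime"]
            df["persisted"] = truth["persisted"]
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
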