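"""Model parameters, state types, per-capita rates and the mean-field ODE.

The model describes a cancer cell population structured into a
proliferative aneuploid state (2N+, count ``x1``) and a non-dividing,
therapy-resistant polyaneuploid state (PACC, count ``x2``), with a
continuous drug-resistance trait ``v`` shared by the whole population.
One simulation count represents 10^7 cells, so the carrying capacity
``K = 100`` corresponds to 10^9 cells.

The deterministic skeleton is

    dx1/dt = r*x1*(K - x1 - x2)/K  -  gamma*x1  -  x1*m/(lam + b*v)
             -  c21*x1*m/(lam + b*v)  +  2*c12*x2
    dx2/dt = gamma*eta*x1  +  c21*eta*x1*m/(lam + b*v)  -  c12*x2

2N+ cells grow logistically (inhibited equally by both states), die
from drug at the Michaelis-Menten kill rate m/(lam + b*v), transition
to the PACC state both obligately (rate gamma) and facultatively (in
proportion to drug kill, scaling c21), and each depolyploidizing PACC
returns two 2N+ cells.  Only a fraction ``eta`` of 2N+ -> PACC
transitions succeed; failures die.  PACCs themselves never die.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp


@dataclass
class Parameters:
    """Model constants plus numerical controls.

    Defaults are the standard simulation values; ``m`` (drug dosage) and
    ``zeta`` (SGM threshold) are scenario-dependent.

    Attributes
    ----------
    r : intrinsic 2N+ growth rate, per day.
    K : carrying capacity, units of 10^7 cells.
    gamma : obligate 2N+ -> PACC transition rate, per day.
    m : drug dosage, per day.
    lam : baseline level of resistance (dimensionless).
    b : efficacy of the evolved resistance strategy (dimensionless).
    c21 : facultative 2N+ -> PACC transition scaling rate, per day.
    c12 : PACC -> 2N+ depolyploidization rate, per day.
    eta : probability a 2N+ -> PACC transition succeeds (failures die).
    mu : mutation probability per division / depolyploidization.
    sigma1 : mutational breadth at 2N+ division.
    sigma2 : mutational breadth at PACC depolyploidization.
    zeta : SGM threshold on the drug-kill rate, per day.
    dt : stochastic step length, days.
    """

    r: float = 0.6
    K: float = 100.0
    gamma: float = 0.02
    m: float = 0.0
    lam: float = 1.0
    b: float = 1.0
    c21: float = 0.7
    c12: float = 0.2
    eta: float = 0.7
    mu: float = 0.05
    sigma1: float = 0.01
    sigma2: float = 0.05
    zeta: float = 0.4
    dt: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r", "K", "gamma", "m", "lam", "b", "c21", "c12",
                     "sigma1", "sigma2", "zeta", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        return cls(**d)


@dataclass
class PopulationState:
    """Counts of 2N+ (`x1`) and PACC (`x2`) cells plus the resident trait.

    Counts are integers in units of 10^7 cells; ``v >= 0`` is the
    resistance strategy; ``t`` is simulation time in days.
    """

    x1: int = 0
    x2: int = 0
    v: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError("cell counts must be non-negative")
        if int(self.x1) != self.x1 or int(self.x2) != self.x2:
            raise ValueError("cell counts must be integers")
        self.x1 = int(self.x1)
        self.x2 = int(self.x2)
        if self.v < 0:
            raise ValueError("resistance trait must be non-negative")

    @property
    def extinct(self) -> bool:
        return self.x1 + self.x2 == 0


@dataclass
class TherapySchedule:
    """Piecewise-constant dose function m(t).

    ``kind`` is one of ``none``, ``continuous`` (on for start <= t < stop)
    or ``intermittent`` (starting at ``start``, on for ``on_len`` days
    then off for ``off_len`` days, repeating).  Intervals are half-open
    [on, off).
    """

    kind: Literal["none", "continuous", "intermittent"] = "none"
    dose: float = 0.0
    start: float = 0.0
    stop: float = math.inf
    on_len: float = 0.0
    off_len: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "continuous", "intermittent"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.kind == "intermittent" and (self.on_len <= 0 or self.off_len < 0):
            raise ValueError("intermittent schedule needs on_len > 0, off_len >= 0")

    def dose_at(self, t: float) -> float:
        """Dose at time ``t`` (per day)."""
        if self.kind == "none" or self.dose == 0.0:
            return 0.0
        if self.kind == "continuous":
            return self.dose if self.start <= t < self.stop else 0.0
        # intermittent
        if t < self.start or t >= self.stop:
            return 0.0
        phase = (t - self.start) % (self.on_len + self.off_len)
        return self.dose if phase < self.on_len else 0.0

    def breakpoints(self, t0: float, t_end: float) -> list[float]:
        """Times in (t0, t_end) at which the dose changes value."""
        pts: list[float] = []
        if self.kind == "none" or self.dose == 0.0:
            return pts
        if self.kind == "continuous":
            cand = [self.start, self.stop]
        else:
            cand = []
            cycle = self.on_len + self.off_len
            t = self.start
            while t < t_end:
                cand.append(t)
                cand.append(min(t + self.on_len, self.stop))
                if t + self.on_len >= self.stop:
                    break
                t += cycle
        for c in cand:
            if t0 < c < t_end and math.isfinite(c):
                pts.append(c)
        return sorted(set(pts))

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["stop"]):
            d["stop"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TherapySchedule":
        d = dict(d)
        if d.get("stop") is None:
            d["stop"] = math.inf
        return cls(**d)


@dataclass
class RateSet:
    """Population-level event rates (events/day) at a given state.

    The signed logistic term r*x1*(K-x1-x2)/K maps onto exactly one of
    two channels: a birth flux while the population is below carrying
    capacity, or a crowding-death flux above it.  Every component is a
    non-negative stochastic event rate for any valid state, and at
    quasi-equilibrium the logistic channels nearly vanish, so the
    demographic noise of an equilibrated population is dominated by the
    slow PACC-cycling loop rather than by a large birth/death turnover.
    """

    birth: float
    comp_death: float
    drug_death: float
    obligate_out: float
    facultative_out: float
    depoly: float

    def total_2n(self) -> float:
        """Total per-population event rate over the 2N+ channels."""
        return (self.birth + self.comp_death + self.drug_death
                + self.obligate_out + self.facultative_out)


def drug_kill(v: float, m: float, p: Parameters) -> float:
    """Per-capita drug-induced 2N+ death rate m/(lam + b*v), per day.

    Michaelis-Menten decreasing in the resistance trait ``v``.
    """
    if v < 0:
        raise ValueError("resistance trait must be non-negative")
    if m < 0:
        raise ValueError("dose must be non-negative")
    if m == 0.0:
        return 0.0
    return m / (p.lam + p.b * v)


def rates(s: PopulationState, m: float, p: Parameters,
          occupancy: float | None = None) -> RateSet:
    """Population-level event rates at state ``s`` under dose ``m``.

    ``occupancy`` overrides the crowding term's total density (used when
    two populations share the carrying capacity); by default it is the
    population's own x1 + x2.  The eta-thinning of PACC arrivals and the
    +2 yield of depolyploidization are applied at event resolution, not
    here.
    """
    occ = s.x1 + s.x2 if occupancy is None else occupancy
    kill = drug_kill(s.v, m, p)
    growth = p.r * s.x1 * (p.K - occ) / p.K
    return RateSet(
        birth=max(growth, 0.0),
        comp_death=max(-growth, 0.0),
        drug_death=s.x1 * kill,
        obligate_out=p.gamma * s.x1,
        facultative_out=p.c21 * s.x1 * kill,
        depoly=p.c12 * s.x2,
    )


def _ode_rhs(t: float, y: np.ndarray, m: float, v: float, p: Parameters) -> list[float]:
    x1, x2 = max(y[0], 0.0), max(y[1], 0.0)
    kill = m / (p.lam + p.b * v)
    dx1 = (p.r * x1 * (p.K - x1 - x2) / p.K - p.gamma * x1
           - x1 * kill - p.c21 * x1 * kill + 2.0 * p.c12 * x2)
    dx2 = p.gamma * p.eta * x1 + p.c21 * p.eta * x1 * kill - p.c12 * x2
    return [dx1, dx2]


def ode_solve(init: PopulationState, schedule: TherapySchedule, p: Parameters,
              t_end: float, t_eval_step: float = 1.0,
              rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate the mean-field ODE with a fixed trait (no evolution).

    The system is integrated piecewise between dose changes so the
    discontinuities in m(t) are resolved exactly.  Returns a pandas
    DataFrame with columns ``t, x1, x2, v, m_t``; densities are clamped
    at zero.

    Raises RuntimeError with the failure time if the integrator fails.
    """
    import pandas as pd

    if t_end <= init.t:
        raise ValueError("t_end must exceed the initial time")
    seg_edges = [init.t] + schedule.breakpoints(init.t, t_end) + [t_end]
    t_eval = np.arange(init.t, t_end + 0.5 * t_eval_step, t_eval_step)
    t_eval = t_eval[t_eval <= t_end]

    ts_out: list[np.ndarray] = []
    ys_out: list[np.ndarray] = []
    y0 = np.array([float(init.x1), float(init.x2)])
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        m_seg = schedule.dose_at(a)
        seg_eval = t_eval[(t_eval >= a) & (t_eval < b)]
        sol = solve_ivp(_ode_rhs, (a, b), y0, args=(m_seg, init.v, p),
                        method="LSODA", rtol=rtol, atol=atol,
                        t_eval=seg_eval if len(seg_eval) else None,
                        dense_output=False)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed at t={sol.t[-1]:.3f}: {sol.message}")
        if len(seg_eval):
            ts_out.append(sol.t)
            ys_out.append(np.clip(sol.y, 0.0, None))
        # restart from the segment endpoint
        end = solve_ivp(_ode_rhs, (a, b), y0, args=(m_seg, init.v, p),
                        method="LSODA", rtol=rtol, atol=atol,
                        t_eval=[b])
        if not end.success:
            raise RuntimeError(f"ODE integration failed at t={end.t[-1]:.3f}: {end.message}")
        y0 = np.clip(end.y[:, -1], 0.0, None)
    # include the final time point
    ts_out.append(np.array([t_end]))
    ys_out.append(y0.reshape(2, 1))

    t_all = np.concatenate(ts_out)
    y_all = np.concatenate(ys_out, axis=1)
    return pd.DataFrame({
        "t": t_all,
        "x1": y_all[0],
        "x2": y_all[1],
        "v": init.v,
        "m_t": [schedule.dose_at(t) for t in t_all],
    })


def equilibrium_no_drug(p: Parameters) -> tuple[float, float]:
    """Positive equilibrium (x1*, x2*) of the mean-field system at m=0.

    Setting dx2/dt = 0 gives x2* = gamma*eta*x1*/c12; substituting into
    dx1/dt = 0 yields a closed form for x1*.
    """
    q = p.gamma * p.eta / p.c12  # x2*/x1*
    # r*(K - (1+q) x1)/K - gamma + 2*c12*q = 0
    x1 = p.K * (p.r - p.gamma + 2.0 * p.c12 * q) / (p.r * (1.0 + q))
    return max(x1, 0.0), max(q * x1, 0.0)
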