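"""Fixed-step birth-death-switching simulation of the structured population.

Each step of length ``dt`` (one day by default, matching the model's
time step) treats the 2N+ channels as competing risks: a cell
experiences at most one event per step, with total event probability
1 - exp(-R*dt) split across channels in proportion to their rates,
aggregated over cells as one multinomial draw.  The channels are the
signed logistic flux (division below carrying capacity, crowding death
above it), drug death, and the obligate and facultative PACC
transitions.  Each PACC independently depolyploidizes with probability
1 - exp(-c12*dt) (vetoed wholesale during the SGM blocked phase).
Every 2N+ -> PACC attempt succeeds with probability eta, failures die;
every depolyploidization removes one PACC and adds two 2N+ cells.
Realized divisions and depolyploidizations feed the mutation machinery.

Randomness is a numpy Generator owned by the caller; identical seeds
give bit-identical trajectories.  An extinct population makes no draws,
so an empty competitor leaves the other population's stream untouched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .model import Parameters, PopulationState, TherapySchedule, drug_kill
from .evolution import (EvolutionConfig, et_mutation_update, sgm_gate,
                        sgm_internal_update)


@dataclass
class StepEvents:
    """Realized event counts in one step."""

    n_birth: int = 0
    n_comp_death: int = 0
    n_drug_death: int = 0
    n_obligate_attempt: int = 0
    n_obligate_success: int = 0
    n_facultative_attempt: int = 0
    n_facultative_success: int = 0
    n_depoly: int = 0


@dataclass
class TrialResult:
    """Daily-sampled trajectory of one stochastic trial."""

    times: np.ndarray
    x1_series: np.ndarray
    x2_series: np.ndarray
    v_series: np.ndarray
    m_series: np.ndarray
    extinct: bool
    extinction_time: float | None
    seed: object = None
    engine: str = "ET"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.times,
            "x1": self.x1_series,
            "x2": self.x2_series,
            "v": self.v_series,
            "m_t": self.m_series,
            "engine": self.engine,
        })

    def write_csv(self, path, params: Parameters | None = None) -> None:
        """CSV trajectory plus a JSON sidecar with run metadata."""
        self.to_frame().to_csv(path, index=False)
        sidecar = str(path) + ".json"
        meta = {
            "seed": self.seed if isinstance(self.seed, (int, type(None))) else str(self.seed),
            "engine": self.engine,
            "extinct": bool(self.extinct),
            "extinction_time": self.extinction_time,
        }
        if params is not None:
            meta["parameters"] = params.to_dict()
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=2)


def step(s: PopulationState, m: float, p: Parameters, cfg: EvolutionConfig,
         rng: np.random.Generator,
         occupancy: float | None = None) -> tuple[PopulationState, StepEvents]:
    """Advance one population by dt under dose m; returns (state, events).

    ``occupancy`` overrides the total density in the crowding term when
    populations share the carrying capacity.  Extinction is absorbing:
    an extinct input advances in time with zero events and no draws.
    """
    ev = StepEvents()
    if s.x1 == 0 and s.x2 == 0:
        return PopulationState(0, 0, s.v, s.t + p.dt), ev

    occ = s.x1 + s.x2 if occupancy is None else occupancy
    kill = drug_kill(s.v, m, p)
    v = s.v
    x1, x2 = s.x1, s.x2

    blocked = cfg.engine == "SGM" and not sgm_gate(v, m, p, cfg.zeta)

    n_ob_succ = n_fac_succ = n_depoly = 0
    if x1 > 0:
        growth = p.r * (p.K - occ) / p.K
        lam_birth = max(growth, 0.0)
        lam_cd = max(-growth, 0.0)
        lam_dd = kill
        lam_ob = p.gamma
        lam_fac = p.c21 * kill
        total = lam_birth + lam_cd + lam_dd + lam_ob + lam_fac
        if total > 0:
            p_evt = -math.expm1(-total * p.dt)
            scale = p_evt / total
            probs = (lam_birth * scale, lam_cd * scale, lam_dd * scale,
                     lam_ob * scale, lam_fac * scale, 1.0 - p_evt)
            counts = rng.multinomial(x1, probs)
            ev.n_birth = int(counts[0])
            ev.n_comp_death = int(counts[1])
            ev.n_drug_death = int(counts[2])
            ev.n_obligate_attempt = int(counts[3])
            ev.n_facultative_attempt = int(counts[4])
            if ev.n_obligate_attempt:
                n_ob_succ = int(rng.binomial(ev.n_obligate_attempt, p.eta))
            if ev.n_facultative_attempt:
                n_fac_succ = int(rng.binomial(ev.n_facultative_attempt, p.eta))
            ev.n_obligate_success = n_ob_succ
            ev.n_facultative_success = n_fac_succ

    if x2 > 0 and not blocked:
        n_depoly = int(rng.binomial(x2, -math.expm1(-p.c12 * p.dt)))
        ev.n_depoly = n_depoly

    x1_new = (x1 + ev.n_birth - ev.n_comp_death - ev.n_drug_death
              - ev.n_obligate_attempt - ev.n_facultative_attempt + 2 * n_depoly)
    x2_new = x2 + n_ob_succ + n_fac_succ - n_depoly

    v_new = et_mutation_update(v, ev.n_birth, n_depoly, m, p, rng)
    if blocked:
        v_new = sgm_internal_update(v_new, x2, m, p, cfg, rng, p.dt)

    return PopulationState(x1_new, x2_new, v_new, s.t + p.dt), ev


def run_trial(init: PopulationState, schedule: TherapySchedule, p: Parameters,
              cfg: EvolutionConfig, t_end: float, seed,
              record_every: float = 1.0) -> TrialResult:
    """Run one trial from init.t to t_end, sampling daily by default.

    ``seed`` may be an int or a numpy SeedSequence; the trial draws from
    the first child stream spawned from it — the same stream population
    0 uses in a competition run — so identical seeds give identical
    results in either setting.
    """
    if t_end <= init.t:
        raise ValueError("t_end must exceed the initial time")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    n_steps = int(round((t_end - init.t) / p.dt))
    rec_stride = max(1, int(round(record_every / p.dt)))
    n_rec = n_steps // rec_stride + 1

    times = np.empty(n_rec)
    x1s = np.empty(n_rec, dtype=np.int64)
    x2s = np.empty(n_rec, dtype=np.int64)
    vs = np.empty(n_rec)
    ms = np.empty(n_rec)

    s = init
    extinct = s.extinct
    ext_time = s.t if extinct else None
    times[0], x1s[0], x2s[0], vs[0] = s.t, s.x1, s.x2, s.v
    ms[0] = schedule.dose_at(s.t)

    k = 1
    for i in range(1, n_steps + 1):
        if not extinct:
            m = schedule.dose_at(s.t)
            s, _ = step(s, m, p, cfg, rng)
            if s.extinct:
                extinct = True
                ext_time = s.t
        else:
            s = PopulationState(0, 0, s.v, s.t + p.dt)
        if i % rec_stride == 0:
            times[k], x1s[k], x2s[k], vs[k] = s.t, s.x1, s.x2, s.v
            ms[k] = schedule.dose_at(s.t)
            k += 1

    return TrialResult(times=times, x1_series=x1s, x2_series=x2s,
                       v_series=vs, m_series=ms, extinct=extinct,
                       extinction_time=ext_time,
                       seed=seed if isinstance(seed, int) else None,
                       engine=cfg.engine)


def run_competition_trial(inits: list[PopulationState],
                          schedule: TherapySchedule, p: Parameters,
                          cfgs: list[EvolutionConfig], t_end: float,
                          seed, record_every: float = 1.0) -> list[TrialResult]:
    """Run coupled populations sharing the carrying capacity.

    Each population owns a child stream spawned from the trial seed by
    its index, so a population initialized empty consumes no randomness
    and the remaining population reproduces its single-population run
    bit for bit.
    """
    if len(inits) != len(cfgs):
        raise ValueError("one EvolutionConfig per population required")
    t0 = inits[0].t
    if any(s.t != t0 for s in inits):
        raise ValueError("populations must share the initial time")
    if t_end <= t0:
        raise ValueError("t_end must exceed the initial time")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(child) for child in ss.spawn(len(inits))]

    n_steps = int(round((t_end - t0) / p.dt))
    rec_stride = max(1, int(round(record_every / p.dt)))
    n_rec = n_steps // rec_stride + 1

    n_pop = len(inits)
    times = np.empty(n_rec)
    x1s = [np.empty(n_rec, dtype=np.int64) for _ in range(n_pop)]
    x2s = [np.empty(n_rec, dtype=np.int64) for _ in range(n_pop)]
    vs = [np.empty(n_rec) for _ in range(n_pop)]
    ms = np.empty(n_rec)

    states = list(inits)
    extinct = [s.extinct for s in states]
    ext_time: list[float | None] = [s.t if s.extinct else None for s in states]

    times[0] = t0
    ms[0] = schedule.dose_at(t0)
    for j, s in enumerate(states):
        x1s[j][0], x2s[j][0], vs[j][0] = s.x1, s.x2, s.v

    k = 1
    for i in range(1, n_steps + 1):
        t = states[0].t
        m = schedule.dose_at(t)
        occ = sum(s.x1 + s.x2 for s in states)
        for j in range(n_pop):
            s = states[j]
            if extinct[j]:
                states[j] = PopulationState(0, 0, s.v, s.t + p.dt)
                continue
            s_new, _ = step(s, m, p, cfgs[j], rngs[j], occupancy=occ)
            states[j] = s_new
            if s_new.extinct:
                extinct[j] = True
                ext_time[j] = s_new.t
        if i % rec_stride == 0:
            times[k] = states[0].t
            ms[k] = schedule.dose_at(states[0].t)
            for j, s in enumerate(states):
                x1s[j][k], x2s[j][k], vs[j][k] = s.x1, s.x2, s.v
            k += 1

    return [TrialResult(times=times.copy(), x1_series=x1s[j], x2_series=x2s[j],
                        v_series=vs[j], m_series=ms.copy(), extinct=extinct[j],
                        extinction_time=ext_time[j],
                        seed=seed if isinstance(seed, int) else None,
                        engine=cfgs[j].engine)
            for j in range(n_pop)]
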