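"""Experiment suite: therapy scenarios, competition, dose and zeta sweeps.

Every quantitative readout is a Monte-Carlo extinction fraction over
independent seeded trials (100 by default).  Single-population
scenarios initialize 10 2N+ cells with no PACCs and trait 0 and run to
day 1000 with therapy in [200, 800); competition scenarios couple one
ET and one SGM population through a shared crowding term (each
population's density-dependent death uses the summed occupancy of all
four compartments against the common K), start both at 100 2N+ cells,
treat over [0, 600) and run to day 800.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .model import Parameters, PopulationState, TherapySchedule
from .evolution import EvolutionConfig
from .engine import TrialResult, run_trial, run_competition_trial

SCENARIOS = ("no_therapy", "continuous", "intermittent", "competition",
             "dose_sweep", "zeta_sweep")


@dataclass
class ExperimentSpec:
    """A fully specified, seedable experiment."""

    scenario: str
    engines: tuple[str, ...]
    schedule: TherapySchedule
    params: Parameters
    init: PopulationState
    n_trials: int = 100
    base_seed: int = 0
    t_end: float = 1000.0
    zeta: float = 0.4
    sgm_proposal_rate_factor: float = 1.0
    sweep_values: tuple[float, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if self.scenario in ("competition", "dose_sweep"):
            if tuple(self.engines) != ("ET", "SGM"):
                raise ValueError("competition requires exactly the (ET, SGM) pair")

    def evolution_config(self, engine: str) -> EvolutionConfig:
        return EvolutionConfig(engine=engine, zeta=self.zeta,
                               sgm_proposal_rate_factor=self.sgm_proposal_rate_factor)


@dataclass
class ExperimentSummary:
    """Aggregate of an experiment: extinction statistics and trajectories.

    Keys of the per-engine dicts are engine names ("ET", "SGM") or, for
    sweeps, (sweep_value, engine) tuples.
    """

    spec: ExperimentSpec
    extinction_count: dict
    n_trials: int
    trials: dict = field(default_factory=dict)
    sweep_values: tuple[float, ...] = ()

    @property
    def extinction_fraction(self) -> dict:
        return {k: c / self.n_trials for k, c in self.extinction_count.items()}

    def to_json_dict(self) -> dict:
        def _key(k):
            return k if isinstance(k, str) else "|".join(map(str, k))

        return {
            "name": self.spec.name,
            "scenario": self.spec.scenario,
            "n_trials": self.n_trials,
            "base_seed": self.spec.base_seed,
            "parameters": self.spec.params.to_dict(),
            "schedule": self.spec.schedule.to_dict(),
            "zeta": self.spec.zeta,
            "extinction_count": {_key(k): int(v) for k, v in self.extinction_count.items()},
            "extinction_fraction": {_key(k): v for k, v in self.extinction_fraction.items()},
            "sweep_values": list(self.sweep_values),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    def tidy_frame(self):
        """One row per trial: engine, dose, zeta, seed, outcome, final trait."""
        import pandas as pd

        rows = []
        for key, trials in self.trials.items():
            if isinstance(key, str):
                sweep_val, engine = None, key
            else:
                sweep_val, engine = key
            for i, tr in enumerate(trials):
                rows.append({
                    "scenario": self.spec.scenario,
                    "engine": engine,
                    "dose": self.spec.schedule.dose if sweep_val is None else sweep_val,
                    "zeta": self.spec.zeta,
                    "seed": self.spec.base_seed + i,
                    "extinct": tr.extinct,
                    "extinction_time": tr.extinction_time,
                    "final_v": float(tr.v_series[-1]),
                })
        return pd.DataFrame(rows)


def _trial_seed(base_seed: int, i: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(base_seed + i)


def run_single_population(spec: ExperimentSpec,
                          keep_trials: bool = True) -> ExperimentSummary:
    """Run n_trials independent trials per engine (or per zeta for sweeps)."""
    if spec.scenario not in ("no_therapy", "continuous", "intermittent", "zeta_sweep"):
        raise ValueError(f"scenario {spec.scenario!r} is not single-population")

    counts: dict = {}
    trials: dict = {}
    if spec.scenario == "zeta_sweep":
        jobs = [((z, "SGM"), replace(spec, zeta=z).evolution_config("SGM"))
                for z in spec.sweep_values]
    else:
        jobs = [(eng, spec.evolution_config(eng)) for eng in spec.engines]

    for key, cfg in jobs:
        results = [run_trial(spec.init, spec.schedule, spec.params, cfg,
                             spec.t_end, _trial_seed(spec.base_seed, i))
                   for i in range(spec.n_trials)]
        counts[key] = sum(tr.extinct for tr in results)
        if keep_trials:
            trials[key] = results
    return ExperimentSummary(spec=spec, extinction_count=counts,
                             n_trials=spec.n_trials, trials=trials,
                             sweep_values=spec.sweep_values)


def run_competition(spec: ExperimentSpec,
                    keep_trials: bool = True) -> ExperimentSummary:
    """Compete one ET and one SGM population under a shared K.

    Both populations start from ``spec.init``, share parameters and the
    therapy schedule, and evolve their own resident traits; trial i
    spawns one child stream per population from seed base_seed + i.
    """
    if spec.scenario != "competition":
        raise ValueError("spec.scenario must be 'competition'")
    cfgs = [spec.evolution_config("ET"), spec.evolution_config("SGM")]
    counts = {"ET": 0, "SGM": 0}
    trials: dict = {"ET": [], "SGM": []}
    for i in range(spec.n_trials):
        et_tr, sgm_tr = run_competition_trial(
            [spec.init, spec.init], spec.schedule, spec.params, cfgs,
            spec.t_end, _trial_seed(spec.base_seed, i))
        counts["ET"] += et_tr.extinct
        counts["SGM"] += sgm_tr.extinct
        if keep_trials:
            trials["ET"].append(et_tr)
            trials["SGM"].append(sgm_tr)
    return ExperimentSummary(spec=spec, extinction_count=counts,
                             n_trials=spec.n_trials, trials=trials)


def classify_regime(k_et: int, k_sgm: int, n: int, alpha: float = 0.05) -> str:
    """Label a dose by which engine dies more, beyond binomial noise.

    Two-proportion z-test on extinction counts: "low_selection" if ET
    goes extinct significantly less often than SGM (ET favored),
    "high_selection" if significantly more (SGM favored), otherwise
    "no_selection".
    """
    from statsmodels.stats.proportion import proportions_ztest

    if k_et == k_sgm:
        return "no_selection"
    stat, pval = proportions_ztest([k_et, k_sgm], [n, n])
    if pval >= alpha:
        return "no_selection"
    return "low_selection" if k_et < k_sgm else "high_selection"


def run_dose_sweep(spec: ExperimentSpec,
                   keep_trials: bool = False) -> ExperimentSummary:
    """Repeat the competition experiment across a dose grid.

    Returns per-(dose, engine) extinction counts plus a regime label per
    dose stored in the summary's spec-independent ``regimes`` attribute
    of the JSON dict.
    """
    if spec.scenario != "dose_sweep":
        raise ValueError("spec.scenario must be 'dose_sweep'")
    doses = spec.sweep_values or tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
    counts: dict = {}
    trials: dict = {}
    for d in doses:
        sub = replace(spec, scenario="competition",
                      schedule=replace(spec.schedule, dose=float(d)),
                      sweep_values=())
        summ = run_competition(sub, keep_trials=keep_trials)
        counts[(float(d), "ET")] = summ.extinction_count["ET"]
        counts[(float(d), "SGM")] = summ.extinction_count["SGM"]
        if keep_trials:
            trials[(float(d), "ET")] = summ.trials["ET"]
            trials[(float(d), "SGM")] = summ.trials["SGM"]
    out = ExperimentSummary(spec=spec, extinction_count=counts,
                            n_trials=spec.n_trials, trials=trials,
                            sweep_values=tuple(float(d) for d in doses))
    return out


def regimes_by_dose(summary: ExperimentSummary, alpha: float = 0.05) -> dict:
    """Regime classification for each dose of a dose-sweep summary."""
    out = {}
    for d in summary.sweep_values:
        out[d] = classify_regime(summary.extinction_count[(d, "ET")],
                                 summary.extinction_count[(d, "SGM")],
                                 summary.n_trials, alpha=alpha)
    return out


def run_experiment(spec: ExperimentSpec, keep_trials: bool = True) -> ExperimentSummary:
    """Dispatch on the scenario."""
    if spec.scenario == "competition":
        return run_competition(spec, keep_trials=keep_trials)
    if spec.scenario == "dose_sweep":
        return run_dose_sweep(spec, keep_trials=keep_trials)
    return run_single_population(spec, keep_trials=keep_trials)


def fixture_specs(n_trials: int = 100, base_seed: int = 0,
                  dt: float | None = None) -> dict[str, ExperimentSpec]:
    """Ready-made specs for the published scenario catalog.

    fig3a  no therapy, both engines, zeta=0.4
    fig3b  continuous m=0.8 over [200, 800), zeta=0.4
    fig3c  intermittent m=0.8, 100 on / 100 off from day 200, zeta=0.4
    fig4a  continuous m=0.6 over [200, 800), zeta=0.4
    fig4b  continuous m=1 over [200, 800), zeta=0.4
    fig5   SGM zeta sweep {0.2, 0.4, 0.6} at continuous m=1
    fig6a  ET-vs-SGM competition, m=0.6 over [0, 600), zeta=0.2, t_end=800
    fig6b  same at m=1
    fig7   competition dose sweep m in {0, 0.1, ..., 1}, zeta=0.2
    """
    p = Parameters() if dt is None else Parameters(dt=dt)
    init10 = PopulationState(x1=10, x2=0, v=0.0, t=0.0)
    init100 = PopulationState(x1=100, x2=0, v=0.0, t=0.0)
    both = ("ET", "SGM")
    window = dict(start=200.0, stop=800.0)

    def cont(dose):
        return TherapySchedule(kind="continuous", dose=dose, **window)

    comp_sched = TherapySchedule(kind="continuous", dose=0.6, start=0.0, stop=600.0)

    specs = {
        "fig3a": ExperimentSpec("no_therapy", both, TherapySchedule(kind="none"),
                                p, init10, n_trials, base_seed, 1000.0, 0.4,
                                name="fig3a"),
        "fig3b": ExperimentSpec("continuous", both, cont(0.8),
                                p, init10, n_trials, base_seed, 1000.0, 0.4,
                                name="fig3b"),
        "fig3c": ExperimentSpec("intermittent", both,
                                TherapySchedule(kind="intermittent", dose=0.8,
                                                start=200.0, on_len=100.0,
                                                off_len=100.0),
                                p, init10, n_trials, base_seed, 1000.0, 0.4,
                                name="fig3c"),
        "fig4a": ExperimentSpec("continuous", both, cont(0.6),
                                p, init10, n_trials, base_seed, 1000.0, 0.4,
                                name="fig4a"),
        "fig4b": ExperimentSpec("continuous", both, cont(1.0),
                                p, init10, n_trials, base_seed, 1000.0, 0.4,
                                name="fig4b"),
        "fig5": ExperimentSpec("zeta_sweep", ("SGM",), cont(1.0),
                               p, init10, n_trials, base_seed, 1000.0, 0.4,
                               sweep_values=(0.2, 0.4, 0.6), name="fig5"),
        "fig6a": ExperimentSpec("competition", both, comp_sched,
                                p, init100, n_trials, base_seed, 800.0, 0.2,
                                name="fig6a"),
        "fig6b": ExperimentSpec("competition", both,
                                replace(comp_sched, dose=1.0),
                                p, init100, n_trials, base_seed, 800.0, 0.2,
                                name="fig6b"),
        "fig7": ExperimentSpec("dose_sweep", both, replace(comp_sched, dose=0.0),
                               p, init100, n_trials, base_seed, 800.0, 0.2,
                               sweep_values=tuple(np.round(np.arange(0.0, 1.01, 0.1), 10)),
                               name="fig7"),
    }
    return specs
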