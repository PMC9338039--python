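"""Trait machinery: mutation, trait substitution (ET) and the SGM gate.

Both inheritance engines treat the population as monomorphic in the
resistance trait ``v`` and evolve it by trait substitution in the
adaptive-dynamics sense: a mutant replaces the resident iff it has
strictly higher invasion fitness at the current dose.  Because ``v``
enters the model only through the drug-kill term, a mutant is fitter
exactly when its kill rate is lower, i.e. when ``v_candidate >
v_resident`` under positive dose; at zero dose no mutant ever invades.

Under evolutionary triage (ET) mutants arise at realized divisions
(breadth sigma1) and depolyploidizations (breadth sigma2), each with
probability ``mu``.  Under self-genetic modification (SGM), while the
drug-kill rate is at or above the threshold ``zeta`` the PACCs withhold
depolyploidization ("stable PACC state") and instead hill-climb the
trait internally by trial-and-error; once kill drops below ``zeta`` the
gate opens and the dynamics revert to plain ET.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .model import Parameters, PopulationState, drug_kill

Engine = Literal["ET", "SGM"]


@dataclass
class EvolutionConfig:
    """Engine selection and SGM-specific knobs.

    ``zeta`` mirrors Parameters.zeta and is the drug-kill level below
    which PACCs are allowed to depolyploidize under SGM (ET ignores it).
    ``sgm_proposal_rate_factor`` scales the internal trial-and-error
    proposal rate relative to the mutational opportunity the vetoed
    depolyploidizations would have provided (mu * c12 * x2 per day).
    """

    engine: Engine = "ET"
    zeta: float = 0.4
    sgm_proposal_rate_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.engine not in ("ET", "SGM"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.zeta < 0:
            raise ValueError("zeta must be non-negative")
        if self.sgm_proposal_rate_factor < 0:
            raise ValueError("sgm_proposal_rate_factor must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvolutionConfig":
        return cls(**d)


def propose_mutant(v: float, sigma: float, rng: np.random.Generator) -> float:
    """Gaussian mutation around the resident, reflected off zero.

    Returns max(0, v + delta) with delta ~ N(0, sigma^2); the trait
    space is [0, inf).
    """
    if v < 0:
        raise ValueError("resident trait must be non-negative")
    if sigma <= 0:
        raise ValueError("mutation breadth must be positive")
    return max(0.0, v + sigma * rng.standard_normal())


def fitter(v_candidate: float, v_resident: float, m: float, p: Parameters) -> bool:
    """True iff the candidate strictly out-grows the resident at dose m.

    The trait affects per-capita 2N+ growth only through the drug-kill
    term, so positive invasion fitness reduces to a strictly lower kill
    rate.  Ties never substitute, and at m = 0 there is no selection so
    no mutant ever invades.
    """
    if m == 0.0:
        return False
    return drug_kill(v_candidate, m, p) < drug_kill(v_resident, m, p)


def sgm_gate(v: float, m: float, p: Parameters, zeta: float) -> bool:
    """Whether SGM permits depolyploidization: drug kill strictly < zeta.

    The SGM program only engages under drug pressure, so the gate is
    open whenever no dose is applied.  With zeta above the maximum
    possible kill the gate is always open and SGM coincides with ET;
    with zeta = 0 the gate never opens while any drug is applied
    ("hibernation state").
    """
    return m == 0.0 or drug_kill(v, m, p) < zeta


def et_mutation_update(v: float, n_divisions: int, n_depolys: int,
                       m: float, p: Parameters,
                       rng: np.random.Generator) -> float:
    """Trait after one step's worth of ET mutations.

    Each realized division proposes a mutant with probability mu and
    breadth sigma1; each realized depolyploidization likewise with
    breadth sigma2.  The resident is replaced by the best proposal that
    is strictly fitter; deleterious proposals are triaged instantly.
    At zero dose no proposal can invade, so no draws are consumed.
    """
    if m == 0.0 or (n_divisions == 0 and n_depolys == 0):
        return v
    best = v
    n1 = int(rng.binomial(n_divisions, p.mu)) if n_divisions else 0
    n2 = int(rng.binomial(n_depolys, p.mu)) if n_depolys else 0
    for sigma, n in ((p.sigma1, n1), (p.sigma2, n2)):
        for _ in range(n):
            cand = propose_mutant(v, sigma, rng)
            if fitter(cand, best, m, p):
                best = cand
    return best


def sgm_internal_update(v: float, x2: int, m: float, p: Parameters,
                        cfg: EvolutionConfig, rng: np.random.Generator,
                        dt: float) -> float:
    """Trait after one blocked-phase step of internal trial-and-error.

    The number of hypothetical-progeny proposals is Poisson with mean
    ``sgm_proposal_rate_factor * mu * c12 * x2 * dt`` — the mutational
    opportunity the vetoed depolyploidizations would have provided.
    Proposals use breadth sigma2 and are adopted sequentially whenever
    strictly fitter, so the trait hill-climbs within the PACC refuge.
    No progeny are produced and the counts are untouched.
    """
    if x2 == 0:
        return v
    mean = cfg.sgm_proposal_rate_factor * p.mu * p.c12 * x2 * dt
    n = int(rng.poisson(mean))
    for _ in range(n):
        cand = propose_mutant(v, p.sigma2, rng)
        if fitter(cand, v, m, p):
            v = cand
    return v
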