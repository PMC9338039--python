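# paccsim

Stochastic eco-evolutionary simulation of cancer cell populations
structured into a proliferative aneuploid state (**2N+**) and a
non-dividing, therapy-resistant polyaneuploid cancer cell state
(**PACC**), under two competing engines of heritable adaptation:

- **Evolutionary triage (ET)** — Mendelian inheritance: mutants arise at
  cell division and at PACC depolyploidization, and sweep or die by
  selection, so resistance climbs gradually through the mortality of
  less-fit variants.
- **Self-genetic modification (SGM)** — Lamarckian / reverse-transcriptional
  inheritance: under severe drug stress, cells in the PACC state withhold
  progeny and hill-climb a resistance trait internally by trial and error,
  releasing resistant 2N+ progeny only once the drug-kill rate falls below
  a threshold ζ.

The package is aimed at mathematical oncologists and evolutionary
ecologists who want to compare Mendelian and non-traditional inheritance
in a common birth–death-switching framework, and to reproduce therapy,
dose, ζ and head-to-head competition experiments with extinction-rate
statistics.

## Model

Counts are in units of 10⁷ cells. The mean-field skeleton for 2N+ cells
x₁ and PACC cells x₂ with resistance trait v is

```
dx₁/dt = r·x₁·(K − x₁ − x₂)/K − γ·x₁ − x₁·m/(λ + b·v) − c₂₁·x₁·m/(λ + b·v) + 2·c₁₂·x₂
dx₂/dt = γ·η·x₁ + c₂₁·η·x₁·m/(λ + b·v) − c₁₂·x₂
```

2N+ cells grow logistically (inhibited equally by both states), die from
drug at the Michaelis–Menten kill rate m/(λ+bv), enter the PACC state
both obligately (rate γ) and facultatively (proportional to drug kill,
scaling c₂₁), and each depolyploidizing PACC returns **two** 2N+ cells.
A fraction 1−η of attempted polyploidization transitions fails and dies.
PACCs themselves never die.

The stochastic engine advances this system in fixed daily steps as a
competing-risks birth–death-switching process (see `docs/methods.md` for
the exact construction and its validation against the ODE). The trait
evolves by adaptive-dynamics substitution: a mutant (Gaussian step,
breadth σ₁ at division, σ₂ at depolyploidization, probability μ per
event) replaces the resident iff it strictly lowers drug kill. Under
SGM, while drug kill ≥ ζ depolyploidization is vetoed and proposals are
tested internally at the rate the vetoed flux would have supplied.

Defaults: r=0.6/day, K=100, γ=0.02/day, λ=1, b=1, c₂₁=0.7/day,
c₁₂=0.2/day, η=0.7, μ=0.05, σ₁=0.01, σ₂=0.05.

## Worked example

Run the continuous-therapy scenario (dose m=0.8 over days 200–800,
ζ=0.4, 100 trials per engine, populations initialized with ten 2N+
cells):

```
$ paccsim run -e fig3b --seed 0 -o out/fig3b -v
INFO running fig3b (100 trials, seed 0)
INFO extinction ET: 21%
INFO extinction SGM: 0%
wrote out/fig3b
```

21% of ET populations collapse before evolving enough resistance, while
every SGM population survives: the vetoed depolyploidization keeps the
drug-immune PACC pool intact ("stable PACC state") until the internally
evolved trait brings drug kill below ζ, after which resistant 2N+
progeny repopulate. The output directory contains `config.yaml` (re-runs
to identical output), `trials.csv` (one row per trial with extinction
flag, time and final trait) and `summary.json` (extinction counts).
`paccsim list` shows all canned scenarios (no therapy, intermittent
therapy, dose levels, ζ sweep, ET-vs-SGM competition, dose sweep);
`paccsim ode` writes the deterministic reference trajectory and
`paccsim sweep` the competition dose grid. Library use mirrors the CLI:

```python
from paccsim import fixture_specs, run_experiment
summary = run_experiment(fixture_specs(base_seed=0)["fig3b"])
print(summary.extinction_fraction)   # {'ET': 0.21, 'SGM': 0.0}
```

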