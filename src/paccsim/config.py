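"""YAML round-tripping of parameters, schedules and engine settings.

A config file is a mapping with up to three sections::

    parameters:   {r, K, gamma, m, lam, b, c21, c12, eta, mu,
                   sigma1, sigma2, zeta, dt}
    schedule:     {kind, dose, start, stop, on_len, off_len}
    evolution:    {engine, zeta, sgm_proposal_rate_factor}

Keys follow the model's symbol names; omitted keys take defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import Parameters, TherapySchedule
from .evolution import EvolutionConfig


def config_to_dict(params: Parameters | None = None,
                   schedule: TherapySchedule | None = None,
                   evolution: EvolutionConfig | None = None) -> dict:
    out: dict = {}
    if params is not None:
        out["parameters"] = params.to_dict()
    if schedule is not None:
        out["schedule"] = schedule.to_dict()
    if evolution is not None:
        out["evolution"] = evolution.to_dict()
    return out


def save_config(path, params: Parameters | None = None,
                schedule: TherapySchedule | None = None,
                evolution: EvolutionConfig | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(params, schedule, evolution), fh,
                       sort_keys=False)


def load_config(path) -> tuple[Parameters, TherapySchedule, EvolutionConfig]:
    """Load (Parameters, TherapySchedule, EvolutionConfig) from YAML/JSON.

    Missing sections fall back to defaults; unknown keys raise.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    params = Parameters.from_dict(data.get("parameters", {}))
    schedule = TherapySchedule.from_dict(data.get("schedule", {}))
    evo = data.get("evolution", {})
    # keep the single source of truth for zeta when only one is given
    if "zeta" not in evo and "parameters" in data and "zeta" in data["parameters"]:
        evo = {**evo, "zeta": params.zeta}
    evolution = EvolutionConfig.from_dict(evo)
    return params, schedule, evolution
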