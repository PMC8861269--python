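"""Run configuration: schema, defaults, validation, (de)serialization.

The defaults reproduce the reference study conditions: a 10×10 grid, five
actions, utilities [3, 0], depth-4 policies, 16 gradient iterations per time
step, 10 navigation moves, 30 foraging moves, likelihood concentration prior
1/100 in the foraging patch, β prior 1, learning rate 1, gradient step size
1/4, proximity-preference weight 1/4 and 250 ms per movement.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Raised for schema violations; lists the offending keys."""


@dataclass
class RunConfig:
    grid_rows: int = 10
    grid_cols: int = 10
    utilities: list = field(default_factory=lambda: [3.0, 0.0])
    policy_depth: int = 4
    iterations_per_step: int = 16
    navigation_moves: int = 10
    foraging_moves: int = 30
    a_prior: float = 0.01
    transition_prior_scale: Optional[float] = 2.0
    beta_prior: float = 1.0
    eta: float = 1.0
    step_size: float = 0.25
    proximity_weight: float = 0.25
    step_duration_s: float = 0.25
    seed: int = 0
    start_location: int = 90  # bottom-left corner of the default grid
    target_location: int = 54  # Manhattan distance 8 from the default start
    hidden_object_location: Optional[int] = None
    patch_entrance: Optional[int] = None  # grid centre when unset
    ablate_novelty: bool = False
    sample_actions: bool = False
    learn_online: bool = True

    def __post_init__(self) -> None:
        positives = {
            "policy_depth": self.policy_depth,
            "iterations_per_step": self.iterations_per_step,
            "a_prior": self.a_prior,
            "beta_prior": self.beta_prior,
            "eta": self.eta,
            "step_size": self.step_size,
            "step_duration_s": self.step_duration_s,
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
        }
        bad = [k for k, v in positives.items() if v <= 0]
        if self.transition_prior_scale is not None and self.transition_prior_scale <= 0:
            bad.append("transition_prior_scale")
        if not 0 < self.step_size <= 1:
            bad.append("step_size")
        if len(self.utilities) != 2:
            bad.append("utilities")
        if bad:
            raise ConfigError(f"invalid values for keys: {sorted(set(bad))}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config; an empty file yields the default run.

    Unknown keys are rejected with an error that names them.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
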