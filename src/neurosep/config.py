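"""Run configuration: JSON schema, validation and defaults."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

__all__ = ["RunConfig", "load_config", "DEFAULTS"]

COMMANDS = (
    "simulate",
    "dds-test",
    "orthogonality-test",
    "pattern-diff-test",
    "searchlight",
    "group-test",
    "power-study",
)

#: commands whose output depends on random draws and therefore require a seed
STOCHASTIC_COMMANDS = frozenset(
    {"simulate", "dds-test", "pattern-diff-test", "searchlight", "group-test",
     "power-study"}
)

DEFAULTS = {
    "n_shuffles": 200,
    "radius": 3,
    "grid_points": 1000,
    "n_perm": 5000,
    "scale": "proportion",
    "bandwidth": "pooled",
    "regime": "separable",
    "n_channels": 4,
    "effect_size": 1.0,
    "noise_sd": 1.0,
    "n_per_condition": 50,
    "target_dim": "A",
    "tol": 1e-9,
    "replicates": 100,
    "alternative": "greater",
}


@dataclass
class RunConfig:
    command: str
    seed: int | None = None
    out: str = "."
    inputs: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.command not in COMMANDS:
            raise ValueError(
                f"unknown command {self.command!r}; choose from {COMMANDS}"
            )
        if self.command in STOCHASTIC_COMMANDS and self.seed is None:
            raise ValueError(f"command {self.command!r} requires a seed")
        merged = dict(DEFAULTS)
        merged.update(self.settings)
        unknown = set(self.settings) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown settings field(s): {sorted(unknown)}")
        self.settings = merged

    def setting(self, name: str):
        return self.settings[name]

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "seed": self.seed,
            "out": self.out,
            "inputs": dict(self.inputs),
            "settings": dict(self.settings),
        }


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a JSON run configuration.

    Unknown top-level or settings fields raise with the field named;
    defaults (200 shuffles, radius 3, 1,000 grid points, 5,000 group
    permutations) fill anything omitted.
    """
    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError("config must be a JSON object")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    if "command" not in payload:
        raise ValueError("config missing required field 'command'")
    return RunConfig(**payload)
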