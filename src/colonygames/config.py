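"""Run configuration: YAML/JSON in, resolved JSON out, strict validation.

A run config has three sections — ``environment`` (benefit/cost parameters
and shape names), ``learning`` (group size, selection intensity, mutation,
horizon, seed) and ``experiment`` (which analysis to run plus its
options).  Unknown keys are rejected by name; the fully resolved config is
serialized next to every output so a run can be replayed bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .engine import LearningParams
from .payoffs import ConfigurationError, EnvironmentParams

__all__ = ["RunConfig", "load_config", "resolve", "save_resolved"]

EXPERIMENTS = (
    "simulate", "classify", "sweep", "cull", "ad", "streamlines", "efficiency",
)

# benchmark environment used when a config leaves fields out
DEFAULT_ENVIRONMENT: Dict[str, Any] = {
    "b1": 20.0,
    "b2": -6.0,
    "w": 0.3,
    "beta": 3.0,
}

DEFAULT_LEARNING: Dict[str, Any] = {
    "n": 5,
    "N": 100,
    "alpha": 2.0,
    "mu": 0.01,
    "sigma": 0.005,
    "T": 30_000,
    "seed": 0,
}


@dataclass
class RunConfig:
    environment: EnvironmentParams
    learning: LearningParams
    experiment: str = "simulate"
    mode: str = "full"
    options: Dict[str, Any] = field(default_factory=dict)
    output_prefix: str = "run"

    def to_dict(self) -> Dict[str, Any]:
        return {
            "environment": dataclasses.asdict(self.environment),
            "learning": dataclasses.asdict(self.learning),
            "experiment": self.experiment,
            "mode": self.mode,
            "options": self.options,
            "output_prefix": self.output_prefix,
        }


def _merge_section(defaults: Dict[str, Any], given: Dict[str, Any],
                   section: str, allowed: set) -> Dict[str, Any]:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}"
        )
    out = dict(defaults)
    out.update(given)
    return out


def resolve(raw: Optional[Dict[str, Any]] = None) -> RunConfig:
    """Merge a raw config dict over the documented defaults and validate.

    An empty (or missing) config resolves to the benchmark defaults:
    n = 5, alpha = 2, mu = 0.01, sigma = 0.005, T = 30000, N = 100."""
    raw = dict(raw or {})
    top_allowed = {"environment", "learning", "experiment", "mode", "options",
                   "output_prefix"}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")

    env_allowed = {f.name for f in dataclasses.fields(EnvironmentParams)}
    learn_allowed = {f.name for f in dataclasses.fields(LearningParams)}
    env_kwargs = _merge_section(
        DEFAULT_ENVIRONMENT, raw.get("environment") or {}, "environment",
        env_allowed,
    )
    learn_kwargs = _merge_section(
        DEFAULT_LEARNING, raw.get("learning") or {}, "learning", learn_allowed
    )
    experiment = raw.get("experiment", "simulate")
    if experiment not in EXPERIMENTS:
        raise ConfigurationError(
            f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}"
        )
    mode = raw.get("mode", "full")
    try:
        env = EnvironmentParams(**env_kwargs)
        learning = LearningParams(**learn_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(str(exc)) from exc
    return RunConfig(
        environment=env,
        learning=learning,
        experiment=experiment,
        mode=mode,
        options=dict(raw.get("options") or {}),
        output_prefix=str(raw.get("output_prefix", "run")),
    )


def load_config(path) -> RunConfig:
    """Read a YAML (or JSON — valid YAML) config file and resolve it."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is not None and not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    return resolve(raw)


def save_resolved(cfg: RunConfig, path) -> None:
    """Write the fully resolved config as JSON with stable key order."""
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))
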