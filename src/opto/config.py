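"""Configuration loading and validation (TOML or JSON)."""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from .adaptation import LearningParams
from .experiments import ExperimentConfig
from .interaction import PayoffScheme
from .topology import GridSpec

__all__ = ["load_config", "config_to_dict"]

_TOP_KEYS = {
    "experiment",
    "grid",
    "rounds",
    "replications",
    "master_seed",
    "k_values",
    "openness_values",
    "k",
    "payoffs",
    "learning",
    "infection_requires_own_cooperation",
    "threshold",
    "recording_interval",
    "full",
}
_GRID_KEYS = {"width", "height"}
_PAYOFF_KEYS = {
    "mutual_coop_base",
    "mutual_defect",
    "sucker",
    "temptation",
    "P",
    "infection_penalty",
}
_LEARNING_KEYS = {"alpha", "A", "B", "beta", "delta", "transitivity_condition"}


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse a TOML or JSON experiment configuration, applying defaults.

    Defaults follow the model's reference parameterisation: P=9, infection
    penalty -50, alpha=0.2, beta=0.5, delta=0.25, threshold 0.5, and the
    per-experiment grid and round counts. Unknown keys and out-of-range values
    raise a ConfigError naming the offending field.
    """
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = tomllib.loads(text.decode())
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> ExperimentConfig:
    _check_keys(raw, _TOP_KEYS, "config")
    experiment = raw.get("experiment")
    if experiment not in ("sim1", "sim2", "sim3"):
        raise ConfigError(f"experiment must be sim1|sim2|sim3, got {experiment!r}")

    kwargs: dict = {}
    if "grid" in raw:
        _check_keys(raw["grid"], _GRID_KEYS, "grid")
        try:
            kwargs["grid"] = GridSpec(**raw["grid"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"grid: {exc}") from exc
    if "payoffs" in raw:
        _check_keys(raw["payoffs"], _PAYOFF_KEYS, "payoffs")
        try:
            kwargs["payoffs"] = PayoffScheme(**raw["payoffs"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"payoffs: {exc}") from exc

    learning_raw = dict(raw.get("learning", {}))
    _check_keys(learning_raw, _LEARNING_KEYS, "learning")
    scheme = kwargs.get("payoffs", PayoffScheme())
    try:
        kwargs["learning"] = LearningParams.from_scheme(scheme, **learning_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"learning: {exc}") from exc

    for key in (
        "rounds",
        "replications",
        "master_seed",
        "k",
        "threshold",
        "recording_interval",
        "infection_requires_own_cooperation",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("k_values", "openness_values"):
        if key in raw:
            kwargs[key] = tuple(raw[key])

    factory = {
        "sim1": ExperimentConfig.sim1,
        "sim2": ExperimentConfig.sim2,
        "sim3": ExperimentConfig.sim3,
    }[experiment]
    if experiment == "sim3" and raw.get("full"):
        kwargs["full"] = True
    try:
        return factory(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: ExperimentConfig) -> dict:
    """JSON-serialisable echo of a config, sufficient to reproduce a run."""
    return {
        "experiment": config.experiment,
        "grid": {"width": config.grid.width, "height": config.grid.height},
        "rounds": config.rounds,
        "replications": config.replications,
        "master_seed": config.master_seed,
        "k_values": list(config.k_values),
        "openness_values": list(config.openness_values),
        "k": config.k,
        "payoffs": {
            "mutual_coop_base": config.payoffs.mutual_coop_base,
            "mutual_defect": config.payoffs.mutual_defect,
            "sucker": config.payoffs.sucker,
            "temptation": config.payoffs.temptation,
            "P": config.payoffs.P,
            "infection_penalty": config.payoffs.infection_penalty,
        },
        "learning": {
            "alpha": config.learning.alpha,
            "A": config.learning.A,
            "B": config.learning.B,
            "beta": config.learning.beta,
            "delta": config.learning.delta,
            "transitivity_condition": config.learning.transitivity_condition,
        },
        "openness_learning": config.openness_learning,
        "affinity_dynamics": config.affinity_dynamics,
        "infection_requires_own_cooperation": config.infection_requires_own_cooperation,
        "threshold": config.threshold,
        "recording_interval": config.recording_interval,
    }
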