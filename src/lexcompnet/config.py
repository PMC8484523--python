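"""Run configuration: YAML/JSON loading with validation and strict keys."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import SynthConfig


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


@dataclass
class TrainSettings:
    learning_rate: float = 0.4
    momentum: float = 0.4
    nesterov: bool = True
    epochs: int = 5000
    eval_every: int = 100
    batch_size: int | None = None
    loss: str = "mse"
    convergence_patience: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("train.learning_rate must be > 0")
        if self.epochs < 1:
            raise ConfigError("train.epochs must be >= 1")
        if self.loss not in ("mse", "bce"):
            raise ConfigError("train.loss must be 'mse' or 'bce'")


@dataclass
class VwpSettings:
    pct_hi: float = 85.0
    pct_lo: float = 15.0
    rhyme: str = "last-vowel"
    threshold: float = 0.5

    def __post_init__(self):
        if not 0 <= self.pct_lo < self.pct_hi <= 100:
            raise ConfigError("vwp percentiles must satisfy 0 <= lo < hi <= 100")
        if self.rhyme not in ("last-vowel", "final-n"):
            raise ConfigError("vwp.rhyme must be 'last-vowel' or 'final-n'")


@dataclass
class RunConfig:
    """Paths, model dimensions and stage settings for an end-to-end run.

    When the four input paths are omitted, a synthetic dataset is
    generated from ``synth`` instead.  Defaults reproduce the reference
    hyperparameters: learning rate 0.4, momentum 0.4, Nesterov enabled,
    10 phone slots, 20 features, semantic/visual/lexical dims 100/150/200.
    """

    vocab: str | None = None
    features: str | None = None
    semantic: str | None = None
    visual: str | None = None
    out: str = "runs/run"
    n_slots: int = 10
    vis_k: int = 150
    z_cut: float = 2.0
    n_seeds: int = 1
    log_level: str = "INFO"
    train: TrainSettings = field(default_factory=TrainSettings)
    vwp: VwpSettings = field(default_factory=VwpSettings)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self):
        if self.n_seeds < 1:
            raise ConfigError("n_seeds must be >= 1")
        for name in ("vocab", "features", "semantic", "visual"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")


def _build(cls, data: dict, prefix: str = ""):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config key(s): {prefix}{sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if name == "train":
            value = _build(TrainSettings, value or {}, "train.")
        elif name == "vwp":
            value = _build(VwpSettings, value or {}, "vwp.")
        elif name == "synth":
            value = _build(SynthConfig, value or {}, "synth.")
        elif name == "length_range" and isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        if isinstance(e, ConfigError):
            raise
        raise ConfigError(str(e)) from e


def load_config(path) -> RunConfig:
    """Parse a YAML (or JSON, a YAML subset) file into a validated RunConfig."""
    with open(path) as f:
        try:
            data = yaml.safe_load(f) or {}
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse config: {e}") from e
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return _build(RunConfig, data)


def save_config(cfg: RunConfig, path) -> None:
    import json

    data = json.loads(json.dumps(dataclasses.asdict(cfg)))  # tuples -> lists
    with open(path, "w") as f:
        yaml.safe_dump(data, f, sort_keys=False)
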