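"""Training configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a config file."""


@dataclass
class TrainingConfig:
    """All knobs of the two-stage training pipeline.

    The autoencoder is trained on reconstruction MSE for `ae_epochs`
    (default 120, where its loss curve stabilizes); the encoder and
    attention are then frozen and the mixture of experts is trained on the
    attention-weighted latent codes with binary cross-entropy for
    `moe_epochs`.  Setting `joint_finetune` adds an optional third stage
    that backpropagates the classification loss end to end.
    """

    ae_epochs: int = 120
    moe_epochs: int = 100
    finetune_epochs: int = 20
    joint_finetune: bool = False
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    decision_threshold: float = 0.5
    n_experts: int = 4
    hidden_dim: int = 256
    latent_dim: int = 64
    expert_hidden: int = 32

    def __post_init__(self) -> None:
        for name in ("ae_epochs", "moe_epochs", "batch_size", "n_experts",
                     "hidden_dim", "latent_dim", "expert_hidden"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.finetune_epochs < 0:
            raise ConfigError("finetune_epochs must be non-negative")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigError("decision_threshold must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable short hash of the config, recorded in run logs/manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(source: str | Path | dict | None) -> TrainingConfig:
    """Build a TrainingConfig from a YAML file, dict, or None (all defaults).

    Unknown keys raise ConfigError naming the key — typos are never
    silently absorbed.
    """
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {source} must contain a mapping")
    known = {f.name for f in dataclasses.fields(TrainingConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    return TrainingConfig(**data)


def dump_config(cfg: TrainingConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML; round-trips through load_config."""
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
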