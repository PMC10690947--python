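"""Schema-validated JSON run configuration.

A run config is a JSON object with optional nested sections
``{"preprocess", "graph", "model", "training", "simulate"}``; each section
mirrors the corresponding module's config dataclass, and every omitted
field takes the published default (window 1024 at 256 Hz, lambda 0.5,
lr 0.01, 100 epochs, batch 30, patience 10, 5 folds).  Violations are
reported with their JSON path via pydantic.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .data_io import PreprocessConfig
from .graph import GraphConfig
from .model import ArchConfig
from .montage import SCALP_CHANNELS
from .synthetic import SimConfig
from .train_eval import TrainConfig


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessSection(_Section):
    highpass_hz: float = Field(0.5, ge=0)
    notch_hz: float | None = None
    artifact_threshold_uv: float = Field(100.0, gt=0)
    order: int = Field(4, ge=1)

    def build(self) -> PreprocessConfig:
        return PreprocessConfig(**self.model_dump())


class GraphSection(_Section):
    lam: float = Field(0.5, gt=0, description="calibration constant > 0")
    negative_policy: str = "abs"
    feature_mode: str = "bandpower"
    attention_target: str = "features"
    channels: list[str] = Field(default_factory=lambda: list(SCALP_CHANNELS))
    feature_scale_uv: float | None = Field(None, gt=0)

    def build(self) -> GraphConfig:
        d = self.model_dump()
        d["channels"] = tuple(d["channels"])
        return GraphConfig(**d)


class ModelSection(_Section):
    gcn_dims: list[int] = Field(default_factory=lambda: [64, 32])
    dense_dims: list[int] = Field(default_factory=lambda: [128, 32, 128])
    activation: str = "relu"
    readout: str = "flatten"

    def build(self, n_nodes: int, feature_dim: int) -> ArchConfig:
        return ArchConfig(
            n_nodes=n_nodes, feature_dim=feature_dim,
            gcn_dims=tuple(self.gcn_dims), dense_dims=tuple(self.dense_dims),
            activation=self.activation, readout=self.readout,
        )


class TrainingSection(_Section):
    lr: float = Field(0.01, gt=0)
    epochs: int = Field(100, ge=1)
    batch_size: int = Field(30, ge=1)
    patience: int = Field(10, ge=1)
    k_folds: int = Field(5, ge=2)
    holdout_fraction: float = Field(0.2, ge=0, le=0.5)
    seed: int = 0

    def build(self) -> TrainConfig:
        return TrainConfig(**self.model_dump())


class SimulateSection(_Section):
    n_responsive: int = Field(200, ge=0)
    n_resistant: int = Field(200, ge=0)
    fs: float = Field(256.0, gt=0)
    window: int = Field(1024, ge=2)
    resistant_gain: float = Field(1.6, ge=1)
    alpha_event_rate: float = Field(1.0, ge=0)
    alpha_event_depth: float = Field(0.5, gt=0, lt=1)
    alpha_event_duration: float = Field(0.5, gt=0)
    alpha_event_channels: list[str] = Field(
        default_factory=lambda: ["F3", "C4", "Fz", "P3", "P4"])
    noise_exponent: float = 1.0
    noise_amplitude: float = Field(5.0, gt=0)
    region_coupling: float = Field(0.5, ge=0, le=1)
    seed: int = 0

    def build(self) -> SimConfig:
        d = self.model_dump()
        d.pop("n_responsive")
        d.pop("n_resistant")
        d["alpha_event_channels"] = tuple(d["alpha_event_channels"])
        seed = d.pop("seed")
        return SimConfig(seed=seed, **d)


class RunConfig(_Section):
    """Top-level run configuration with published defaults."""

    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    graph: GraphSection = Field(default_factory=GraphSection)
    model: ModelSection = Field(default_factory=ModelSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    simulate: SimulateSection = Field(default_factory=SimulateSection)


class ConfigError(ValueError):
    """Raised with JSON-path detail when a run config fails validation."""


def load_run_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> RunConfig:
    """Load and validate a JSON run config; None gives all defaults."""
    payload: dict = {}
    if path is not None:
        payload = json.loads(Path(path).read_text())
    if overrides:
        for dotted, value in overrides.items():
            node = payload
            *parents, leaf = dotted.split(".")
            for key in parents:
                node = node.setdefault(key, {})
            node[leaf] = value
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as err:
        lines = [
            f"  $.{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in err.errors()
        ]
        raise ConfigError(
            "invalid run configuration:\n" + "\n".join(lines)
        ) from err
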