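"""Run configuration: one structured object (YAML-serializable) that drives
the full pipeline with a single root seed.

Every parameter has a default, so ``RunConfig()`` runs end-to-end; every
stochastic stage draws from a named substream of ``seed`` (see
:mod:`quathar._rng`), which makes any pipeline output replayable
byte-for-byte from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .evaluate import ClassifierConfig
from .synthetic import SensorNoiseModel

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # simulation
    subjects: int = 8
    location: str = "LB"
    time_scale: float = 1.0
    acc_noise_std: float = 0.2
    gyr_noise_std: float = 0.02
    mag_noise_std: float = 0.01
    gyr_bias: float = 0.01
    sample_rate: float = 50.0
    # attitude filter
    beta: float = 0.1
    q_init_mode: str = "triad"
    # features / classifier
    feature_tags: tuple[str, ...] = ("raw6", "quat4")
    stride: int = 1
    k: int = 5
    n_learners: int = 30
    n_rows: int | None = None
    n_subspace_features: int | None = None
    # bookkeeping
    seed: int = 0
    out_dir: str = "quathar-out"

    def noise_model(self) -> SensorNoiseModel:
        return SensorNoiseModel(
            self.acc_noise_std,
            self.gyr_noise_std,
            self.mag_noise_std,
            np.full(3, self.gyr_bias),
            self.sample_rate,
        )

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            k=self.k,
            n_learners=self.n_learners,
            n_rows=self.n_rows,
            n_subspace_features=self.n_subspace_features,
            seed=self.seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["feature_tags"] = list(self.feature_tags)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "feature_tags" in raw:
            raw["feature_tags"] = tuple(raw["feature_tags"])
        return cls(**raw)
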