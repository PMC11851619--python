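"""Run configuration: one YAML-serializable object driving the pipeline.

Every random consumer (phantom seeds, scale sampling, network
initialization) derives its stream from the single global ``seed``, so a
config file plus a seed fully determines a run.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .network import DecoderConfig, EncoderConfig
from .training import TrainingConfig, desk_training_config

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "fdosr_run"
    seed: int = 0
    # corpus
    n_train: int = 16
    n_val: int = 4
    n_test: int = 8
    grid_size: tuple[int, int, int] = (32, 32, 32)
    profiles: tuple[str, ...] = ("react", "ncssfp", "ssfp", "irssfp")
    noise_sigma: float = 0.01
    # model (desk-scale defaults; the full-size architecture is
    # EncoderConfig()/DecoderConfig() defaults)
    encoder: EncoderConfig = field(
        default_factory=lambda: EncoderConfig(
            n_rdb=2, layers_per_rdb=3, base_channels=32, growth_channels=8, feature_dim=32
        )
    )
    decoder: DecoderConfig = field(
        default_factory=lambda: DecoderConfig(n_layers=4, hidden_width=32)
    )
    training: TrainingConfig = field(default_factory=desk_training_config)
    factors: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed), training=replace(self.training, seed=int(seed)))

    # -- YAML round-trip ----------------------------------------------------
    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        return listify(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "encoder" in d:
            d["encoder"] = EncoderConfig(**d["encoder"])
        if "decoder" in d:
            d["decoder"] = DecoderConfig(**d["decoder"])
        if "training" in d:
            t = dict(d["training"])
            for key in ("scale_range", "patch_size"):
                if isinstance(t.get(key), list):
                    t[key] = tuple(t[key])
            d["training"] = TrainingConfig(**t)
        for key in ("grid_size", "profiles", "factors"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))
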