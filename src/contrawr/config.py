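"""YAML experiment configuration.

A single config file is the source of truth for an experiment; CLI flags
override individual keys.  Unknown keys are rejected (fail fast on typos).
Two hyperparameter bundles are provided: the ``desk`` profile (small
batches, few passes, halved widths — minutes on one CPU) and the ``paper``
profile (batch 256, 100 passes, full widths, lr 2e-4).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .augment import AugmentationPolicy
from .contrastive import ContrastiveConfig
from .encoder import EncoderSpec
from .synthetic import DEFAULT_CLASS_BANDS, SyntheticSpec

__all__ = ["ExperimentConfig", "load_config", "PROFILES"]

PROFILES = {
    "desk": dict(
        batch_size=32, lr=1e-3, epochs=30, conv_widths=(4, 8, 16, 32), proj_dim=32
    ),
    "paper": dict(
        batch_size=256, lr=2e-4, epochs=100, conv_widths=(8, 16, 32, 64), proj_dim=32
    ),
}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Strict):
    n_classes: int = 5
    n_subjects: int = 40
    epochs_per_subject: int = 50
    n_channels: int = 4
    n_samples: int = 3000
    fs: float = 100.0
    noise_sd: float = 1.0
    subject_effect_sd: float = 0.2
    center_jitter_sd: float = 0.3
    seed: int = 0

    def to_spec(self) -> SyntheticSpec:
        return SyntheticSpec(class_bands=DEFAULT_CLASS_BANDS, **self.model_dump())


class SplitSection(_Strict):
    pretrain_frac: float = 0.6
    train_frac: float = 0.2
    test_frac: float = 0.2
    seed: int = 0


class AugmentSection(_Strict):
    enabled_ops: tuple[str, ...] = ("bandpass", "noising", "flipping", "shifting")
    bandpass_low: float = 0.5
    bandpass_high: float = 30.0
    noise_snr_db: tuple[float, float] = (5.0, 20.0)
    flip_pairs: list[tuple[int, int]] | None = None
    max_shift: int | None = None

    def to_policy(self) -> AugmentationPolicy:
        return AugmentationPolicy(**self.model_dump())


class EncoderSection(_Strict):
    stft_window: int | None = None
    stft_hop: int | None = None
    stft_window_fn: str = "hann"
    log_compress: bool = True
    conv_widths: tuple[int, int, int, int] = (4, 8, 16, 32)
    kernel: int = 3
    proj_hidden: int = 64
    proj_dim: int = 32

    def to_spec(self) -> EncoderSpec:
        return EncoderSpec(**self.model_dump())


class ContrastiveSection(_Strict):
    sigma: float = 2.0
    delta: float = 0.2
    temperature: float = 2.0
    ema_lambda: float = 0.99
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 32
    mode: str = "contrawr_plus"
    topx: int | None = None
    exclude_self: bool = False

    def to_config(self) -> ContrastiveConfig:
        return ContrastiveConfig(**self.model_dump())


class ExperimentConfig(_Strict):
    """Top-level experiment description."""

    data: str | None = None  # HDF5 path; None means generate synthetic data
    synthetic: SyntheticSection = SyntheticSection()
    split: SplitSection = SplitSection()
    augment: AugmentSection = AugmentSection()
    encoder: EncoderSection = EncoderSection()
    contrastive: ContrastiveSection = ContrastiveSection()
    epochs: int = 30
    supervised_epochs: int = 30
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    out_dir: str = "runs"

    def apply_profile(self, profile: str) -> "ExperimentConfig":
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
        p = PROFILES[profile]
        cfg = self.model_copy(deep=True)
        cfg.contrastive.batch_size = p["batch_size"]
        cfg.contrastive.lr = p["lr"]
        cfg.epochs = p["epochs"]
        cfg.encoder.conv_widths = p["conv_widths"]
        cfg.encoder.proj_dim = p["proj_dim"]
        return cfg

    def dump_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def load_config(path=None) -> ExperimentConfig:
    """Load a YAML config (or the defaults when ``path`` is None)."""
    if path is None:
        return ExperimentConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return ExperimentConfig(**raw)
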