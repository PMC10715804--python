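"""Synthetic multichannel signals with sleep-stage-like spectral classes.

Each class is defined by one or more band-limited oscillations whose
defaults mimic the canonical AASM stage signatures — wake by alpha
(~10 Hz), N1 by low-amplitude theta (~6 Hz), N2 by sigma-band spindles
(~13 Hz), N3 by high-amplitude delta (~1.5 Hz) and REM by mixed
theta-plus-beta content.  These templates make augmentations behave
plausibly but carry no claim of physiological fidelity; they are fully
configurable.

Channels come in mirror pairs that share the oscillatory component (with
independent additive white noise per channel), so swapping the members of a
pair is label-preserving, as channel flipping assumes.  Each subject
carries a random log-normal gain and a small per-class center-frequency
offset, giving within-subject epochs more in common than between-subject
ones and thereby justifying subject-level splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochDataset

__all__ = ["SyntheticSpec", "bandlimited_oscillation", "generate_dataset", "DEFAULT_CLASS_BANDS"]

# per class: list of (center Hz, bandwidth Hz, RMS amplitude)
DEFAULT_CLASS_BANDS: tuple[tuple[tuple[float, float, float], ...], ...] = (
    ((10.0, 2.0, 1.0),),                  # W  — alpha
    ((6.0, 2.0, 0.7),),                   # N1 — low-amplitude theta
    ((13.0, 2.0, 1.0),),                  # N2 — sigma (spindle band)
    ((1.5, 1.0, 2.0),),                   # N3 — high-amplitude delta
    ((5.0, 2.0, 0.8), (20.0, 4.0, 0.8)),  # R  — mixed theta + beta
)


@dataclass
class SyntheticSpec:
    """Study-condition parameters of the synthetic generator."""

    n_classes: int = 5
    n_subjects: int = 40
    epochs_per_subject: int = 50
    n_channels: int = 4
    n_samples: int = 3000
    fs: float = 100.0
    class_bands: tuple = DEFAULT_CLASS_BANDS
    noise_sd: float = 1.0
    subject_effect_sd: float = 0.2
    center_jitter_sd: float = 0.3  # per-subject band-center offset, Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"need at least 2 classes, got {self.n_classes}")
        if self.n_channels % 2 or self.n_channels < 2:
            raise ValueError(
                f"n_channels must be even (mirror pairs), got {self.n_channels}"
            )
        if len(self.class_bands) < self.n_classes:
            raise ValueError(
                f"{len(self.class_bands)} band templates for {self.n_classes} classes"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for bands in self.class_bands[: self.n_classes]:
            for center, bw, amp in bands:
                if not 0 < center < self.fs / 2:
                    raise ValueError(
                        f"band center {center} Hz outside (0, fs/2={self.fs / 2})"
                    )
                if amp <= 0 and amp != 0:
                    raise ValueError(f"amplitude must be >= 0, got {amp}")


def bandlimited_oscillation(
    center: float, bw: float, amp: float, n: int, fs: float, seed: int
) -> np.ndarray:
    """A narrowband random signal with RMS ``amp``.

    White Gaussian noise is masked in the frequency domain to the band
    [center - bw/2, center + bw/2] (at least one rfft bin always survives)
    and rescaled to the requested RMS, so the amplitude is exact up to
    floating point.  As bw -> 0 this degenerates to a pure sinusoid at the
    surviving bin's frequency.
    """
    if not 0 < center < fs / 2:
        raise ValueError(f"center frequency {center} Hz outside (0, fs/2={fs / 2})")
    if amp == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= center - bw / 2) & (freqs <= center + bw / 2)
    if not mask.any():
        mask[np.argmin(np.abs(freqs - center))] = True
    x = np.fft.irfft(spec * mask, n=n)
    return x * (amp / np.sqrt(np.mean(x**2)))


def generate_dataset(spec: SyntheticSpec) -> EpochDataset:
    """Generate a labeled, subject-structured synthetic dataset.

    Labels cycle 0..K-1 within every subject, so class counts are exactly
    balanced whenever K divides the epochs per subject.  Deterministic given
    ``spec.seed``; the label sequence does not depend on the seed.
    """
    rng = np.random.default_rng(spec.seed)
    k, c, n = spec.n_classes, spec.n_channels, spec.n_samples
    n_total = spec.n_subjects * spec.epochs_per_subject
    signals = np.empty((n_total, c, n), dtype=np.float32)
    labels = np.empty(n_total, dtype=int)
    subjects = np.empty(n_total, dtype=object)

    row = 0
    for s in range(spec.n_subjects):
        gain = float(np.exp(rng.normal(0.0, spec.subject_effect_sd)))
        # subject-specific spectral idiosyncrasy: small band-center offsets
        offsets = rng.normal(0.0, spec.center_jitter_sd, size=k)
        sid = f"S{s:03d}"
        for e in range(spec.epochs_per_subject):
            label = e % k
            epoch = rng.normal(0.0, spec.noise_sd, size=(c, n)) if spec.noise_sd else np.zeros((c, n))
            for center, bw, amp in spec.class_bands[label]:
                center_s = float(np.clip(center + offsets[label], 0.5, spec.fs / 2 - 0.5))
                for pair in range(0, c, 2):
                    osc = bandlimited_oscillation(
                        center_s, bw, amp * gain, n, spec.fs,
                        seed=int(rng.integers(2**31)),
                    )
                    epoch[pair] += osc
                    epoch[pair + 1] += osc
            signals[row] = epoch
            labels[row] = label
            subjects[row] = sid
            row += 1

    names = [f"{'LR'[i % 2]}{i // 2}" for i in range(c)]
    return EpochDataset(
        signals=signals,
        fs=spec.fs,
        subjects=subjects.astype(str),
        labels=labels,
        channel_names=names,
    )
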