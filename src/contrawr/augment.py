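"""Signal augmentations for contrastive pretraining.

Four label-preserving perturbations of a multichannel epoch are supported:

* **bandpass** — zero-phase order-1 Butterworth bandpass, suppressing
  content outside the physiological band of interest;
* **noising** — additive band-limited noise (randomly low- or
  high-frequency) at a controlled per-channel signal-to-noise ratio,
  mimicking physical distortion;
* **flipping** — swapping homologous left/right sensor channels, exploiting
  the lateral symmetry of scalp montages;
* **shifting** — circular time shift of every channel, so spectral content
  and per-channel energy are preserved exactly.

``make_views`` draws, per view, a uniformly random non-empty subset of the
enabled operations (flipping is never applied on its own, since swapping
symmetric channels of an otherwise identical signal carries no contrastive
information) and applies them in a fixed order.  Every stochastic choice is
a pure function of the supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import fft as spfft
from scipy import signal as sps

from .epochs import validate_epoch

__all__ = [
    "AugmentationPolicy",
    "bandpass_filter",
    "add_noise",
    "channel_flip",
    "time_shift",
    "make_views",
    "bandpass_batch",
]

_OPS = ("bandpass", "noising", "flipping", "shifting")
# fixed application order for sampled subsets
_ORDER = {"bandpass": 0, "noising": 1, "flipping": 2, "shifting": 3}

_LOW_NOISE_BAND = (0.0, 2.0)  # Hz; high band is (fs/4, fs/2)


def _check_band(low: float, high: float, fs: float) -> None:
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"invalid band edges: need 0 < low < high < fs/2, got "
            f"low={low}, high={high}, fs/2={fs / 2}"
        )


def _check_pairs(pairs, n_channels: int) -> None:
    used: set[int] = set()
    for i, j in pairs:
        if not (0 <= i < n_channels and 0 <= j < n_channels) or i == j:
            raise ValueError(f"invalid flip pair ({i}, {j}) for {n_channels} channels")
        if i in used or j in used:
            raise ValueError(f"overlapping flip pair ({i}, {j})")
        used.update((i, j))


@dataclass
class AugmentationPolicy:
    """Configuration for the augmentation pipeline.

    ``noise_snr_db`` is a (low, high) range; each noising application draws
    the SNR uniformly from it.  ``max_shift`` and flip pairs default at
    application time from the epoch's sampling rate and channel count
    (``fs/2`` samples, i.e. a quarter second at half the rate, and adjacent
    channel pairs (0,1), (2,3), ...).
    """

    enabled_ops: tuple[str, ...] = ("bandpass", "noising", "flipping", "shifting")
    bandpass_low: float = 0.5
    bandpass_high: float = 30.0
    noise_snr_db: tuple[float, float] = (5.0, 20.0)
    flip_pairs: list[tuple[int, int]] | None = None
    max_shift: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.enabled_ops) - set(_OPS)
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
        if tuple(self.enabled_ops) == ("flipping",):
            raise ValueError("channel flipping cannot be the only enabled augmentation")
        lo, hi = (
            (self.noise_snr_db, self.noise_snr_db)
            if np.isscalar(self.noise_snr_db)
            else self.noise_snr_db
        )
        if lo > hi:
            raise ValueError(f"empty SNR range {self.noise_snr_db}")
        self.noise_snr_db = (float(lo), float(hi))

    def validate_for(self, fs: float, n_channels: int, n_samples: int) -> None:
        if "bandpass" in self.enabled_ops:
            _check_band(self.bandpass_low, self.bandpass_high, fs)
        if self.flip_pairs is not None:
            _check_pairs(self.flip_pairs, n_channels)
        if self.max_shift is not None and not (0 <= self.max_shift < n_samples):
            raise ValueError(
                f"max_shift must satisfy 0 <= max_shift < N, got {self.max_shift}"
            )

    def resolved_flip_pairs(self, n_channels: int) -> list[tuple[int, int]]:
        if self.flip_pairs is not None:
            return list(self.flip_pairs)
        return [(i, i + 1) for i in range(0, n_channels - 1, 2)]

    def resolved_max_shift(self, fs: float, n_samples: int) -> int:
        if self.max_shift is not None:
            return int(self.max_shift)
        return min(int(fs // 2), n_samples - 1)


def bandpass_filter(
    x: np.ndarray, fs: float, low: float, high: float
) -> np.ndarray:
    """Zero-phase order-1 Butterworth bandpass over the last axis.

    Forward-backward application (``filtfilt``) squares the magnitude
    response and cancels the phase, so the output is not time-shifted.
    """
    x = validate_epoch(x, fs)
    _check_band(low, high, fs)
    sos = sps.butter(1, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def add_noise(
    x: np.ndarray,
    fs: float,
    snr_db: float,
    seed: int,
    band: tuple[float, float] | None = None,
) -> np.ndarray:
    """Add band-limited noise at a fixed per-channel SNR (dB).

    When ``band`` is None the realization randomly picks the low ([0, 2] Hz)
    or high ([fs/4, fs/2] Hz) band — extra slow drift or fast hash, the two
    distortions wearable recordings typically pick up.  Deterministic given
    ``seed``.
    """
    x = validate_epoch(x, fs)
    c, n = x.shape
    power = np.mean(x**2, axis=-1)
    if np.any(power == 0):
        raise ValueError("SNR undefined: at least one channel is identically zero")
    rng = np.random.default_rng(seed)
    if band is None:
        band = _LOW_NOISE_BAND if rng.random() < 0.5 else (fs / 4, fs / 2)
    # FFT in the input's precision (float32 stays float32 under scipy.fft)
    white = rng.standard_normal((c, n)).astype(x.dtype, copy=False)
    spec = spfft.rfft(white, axis=-1)
    freqs = spfft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"noise band {band} contains no FFT bins at fs={fs}, N={n}")
    noise = spfft.irfft(spec * mask, n=n, axis=-1)
    noise_power = np.mean(noise**2, axis=-1)
    target_power = power * 10.0 ** (-snr_db / 10.0)
    noise *= np.sqrt(target_power / noise_power)[:, None]
    return x + noise


def channel_flip(x: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Swap the rows of each (i, j) pair; an involution."""
    x = np.asarray(x)
    _check_pairs(pairs, x.shape[0])
    perm = np.arange(x.shape[0])
    for i, j in pairs:
        perm[i], perm[j] = j, i
    return x[perm]


def time_shift(x: np.ndarray, shift: int) -> np.ndarray:
    """Circularly shift every channel by ``shift`` samples (positive = delay)."""
    x = np.asarray(x)
    n = x.shape[-1]
    if abs(shift) >= n:
        raise ValueError(f"|shift| must be < N={n}, got {shift}")
    return np.roll(x, shift, axis=-1)


def _valid_subsets(enabled: tuple[str, ...]) -> list[tuple[str, ...]]:
    subsets = []
    for r in range(1, len(enabled) + 1):
        for combo in combinations(enabled, r):
            if combo == ("flipping",):
                continue
            subsets.append(tuple(sorted(combo, key=_ORDER.get)))
    return subsets


def _augment_once(
    x: np.ndarray,
    fs: float,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
    filtered: np.ndarray | None = None,
) -> np.ndarray:
    enabled = tuple(policy.enabled_ops)
    if not enabled:
        return x.copy()
    subsets = _valid_subsets(enabled)
    ops = subsets[rng.integers(len(subsets))]
    out = x
    for op in ops:
        if op == "bandpass":
            # bandpass is deterministic and always applied first, so a
            # precomputed filtered copy of x may stand in for it
            out = (
                filtered
                if filtered is not None
                else bandpass_filter(out, fs, policy.bandpass_low, policy.bandpass_high)
            )
        elif op == "noising":
            lo, hi = policy.noise_snr_db
            snr = float(rng.uniform(lo, hi))
            out = add_noise(out, fs, snr, seed=int(rng.integers(2**31)))
        elif op == "flipping":
            out = channel_flip(out, policy.resolved_flip_pairs(x.shape[0]))
        elif op == "shifting":
            m = policy.resolved_max_shift(fs, x.shape[1])
            out = time_shift(out, int(rng.integers(-m, m + 1)))
    return out


def bandpass_batch(
    signals: np.ndarray, fs: float, low: float, high: float
) -> np.ndarray:
    """Vectorized :func:`bandpass_filter` over a stack of epochs."""
    _check_band(low, high, fs)
    sos = sps.butter(1, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signals, dtype=float), axis=-1)


def make_views(
    x: np.ndarray,
    fs: float,
    policy: AugmentationPolicy,
    seed: int,
    filtered: np.ndarray | None = None,
    validate: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Produce two independently augmented views of the same epoch.

    The two views consume successive draws from one seeded generator, so the
    pair is a pure function of ``(x, policy, seed)``.  ``filtered`` may carry
    a precomputed ``bandpass_filter(x, ...)`` under the same policy, purely
    as a cache — the output is identical either way.
    """
    if validate:
        x = validate_epoch(x, fs)
        policy.validate_for(fs, x.shape[0], x.shape[1])
    rng = np.random.default_rng(seed)
    v1 = _augment_once(x, fs, policy, rng, filtered)
    v2 = _augment_once(x, fs, policy, rng, filtered)
    return v1, v2
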