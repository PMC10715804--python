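"""Spectrogram encoder ``f`` and projection head ``g``.

An epoch is first turned into a per-channel magnitude spectrogram by a
short-time Fourier transform (Hann window, magnitude, optional ``log1p``
compression), then passed through a small 2-D convolutional network: one
stem convolution followed by three (conv -> ELU -> 2x2 max-pool) blocks and
a global average pool, giving a representation ``h`` of dimension ``d``
equal to the last channel width.  The projector ``g`` is a two-layer
perceptron with ELU; its output is L2-normalized onto the unit hypersphere,
where similarity and the contrastive loss are defined.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import fft as spfft
from scipy.signal.windows import get_window

from . import nn
from .epochs import validate_epoch

__all__ = [
    "EncoderSpec",
    "stft_spectrogram",
    "build_encoder",
    "build_projector",
    "encode",
    "project",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class EncoderSpec:
    """Architecture description of the STFT-CNN encoder and projector.

    ``stft_window``/``stft_hop`` default (at resolve time) to 2 s and 0.5 s
    of samples.  ``conv_widths`` gives the stem width followed by the three
    block widths; the representation dimension ``d`` is the last width
    (global average pooling).  The desk-scale default halves the widths of
    the full-scale (8, 16, 32, 64) stack.
    """

    stft_window: int | None = None
    stft_hop: int | None = None
    stft_window_fn: str = "hann"
    log_compress: bool = True
    conv_widths: tuple[int, int, int, int] = (4, 8, 16, 32)
    kernel: int = 3
    proj_hidden: int = 64
    proj_dim: int = 32

    def __post_init__(self) -> None:
        if len(self.conv_widths) != 4:
            raise ValueError("conv_widths must give a stem width plus 3 block widths")
        if min(self.conv_widths) < 1 or self.proj_dim < 1 or self.proj_hidden < 1:
            raise ValueError("layer widths must be positive")

    @property
    def repr_dim(self) -> int:
        return int(self.conv_widths[-1])

    def resolve_stft(self, fs: float, n_samples: int) -> tuple[int, int]:
        window = self.stft_window if self.stft_window is not None else int(2 * fs)
        hop = self.stft_hop if self.stft_hop is not None else max(1, int(fs // 2))
        if window > n_samples:
            raise ValueError(
                f"STFT window ({window} samples) longer than the epoch ({n_samples})"
            )
        if hop < 1:
            raise ValueError(f"STFT hop must be >= 1, got {hop}")
        return int(window), int(hop)

    def validate_geometry(self, fs: float, n_samples: int) -> tuple[int, int]:
        """Check the conv stack keeps a non-empty feature map.

        Three 2x2 pools halve (floor) the frequency/frame axes, so both must
        start at >= 8; returns the final (F, T) map size.
        """
        window, hop = self.resolve_stft(fs, n_samples)
        f = window // 2 + 1
        t = (n_samples - window) // hop + 1
        for _ in range(3):
            f, t = f // 2, t // 2
        if f < 1 or t < 1:
            raise ValueError(
                f"spectrogram of {window // 2 + 1} x {(n_samples - window) // hop + 1} "
                "(frequency x frames) collapses to an empty map after three 2x2 "
                "pools; use a longer epoch, smaller hop, or smaller window"
            )
        return f, t

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "EncoderSpec":
        d = json.loads(text)
        d["conv_widths"] = tuple(d["conv_widths"])
        return cls(**d)


def stft_spectrogram(
    x: np.ndarray, fs: float, spec: EncoderSpec
) -> np.ndarray:
    """Magnitude spectrogram, shape (C, F, T) with F = window//2 + 1.

    Frames start at sample 0 and advance by ``hop``; only complete frames
    are kept, so T = floor((N - window)/hop) + 1.  Accepts a single epoch
    (C, N) or a batch (B, C, N) — the frequency/frame axes are appended
    either way.
    """
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    single = x.ndim == 2
    if single:
        x = validate_epoch(x, fs)[None].astype(x.dtype)
    window, hop = spec.resolve_stft(fs, x.shape[-1])
    win = get_window(spec.stft_window_fn, window, fftbins=True).astype(x.dtype)
    frames = np.lib.stride_tricks.sliding_window_view(x, window, axis=-1)[
        ..., ::hop, :
    ]
    mag = np.abs(spfft.rfft(frames * win, axis=-1))  # (B, C, T, F)
    if spec.log_compress:
        mag = np.log1p(mag)
    out = np.swapaxes(mag, -1, -2)  # (B, C, F, T)
    return out[0] if single else out


def spectrogram_input(s: np.ndarray) -> np.ndarray:
    """Reorder a (B, C, F, T) spectrogram batch to the network's
    channel-last (B, F, T, C) layout."""
    return np.ascontiguousarray(np.moveaxis(s, 1, -1))


def build_encoder(
    spec: EncoderSpec, n_channels: int, seed: int, dtype=np.float32
) -> nn.Sequential:
    """Instantiate ``f``: stem conv, 3 pooled conv blocks, global average pool.

    The network consumes spectrograms in channel-last (B, F, T, C) layout
    (see :func:`spectrogram_input`).
    """
    rng = np.random.default_rng(seed)
    w0, w1, w2, w3 = spec.conv_widths
    layers: list[nn.Layer] = [
        nn.Conv2d(n_channels, w0, spec.kernel, rng, dtype),
        nn.ELU(),
    ]
    for cin, cout in ((w0, w1), (w1, w2), (w2, w3)):
        layers += [nn.Conv2d(cin, cout, spec.kernel, rng, dtype), nn.ELU(), nn.MaxPool2x2()]
    layers.append(nn.GlobalAvgPool())
    layers[0].skip_input_grad = True  # spectrogram input needs no gradient
    return nn.Sequential(layers)


def build_projector(spec: EncoderSpec, seed: int, dtype=np.float32) -> nn.Sequential:
    """Instantiate ``g``: d -> proj_hidden -> m perceptron (pre-normalization)."""
    rng = np.random.default_rng(seed)
    return nn.Sequential(
        [
            nn.Linear(spec.repr_dim, spec.proj_hidden, rng, dtype),
            nn.ELU(),
            nn.Linear(spec.proj_hidden, spec.proj_dim, rng, dtype),
        ]
    )


def encode(
    x: np.ndarray,
    fs: float,
    spec: EncoderSpec,
    encoder: nn.Sequential,
    batch_size: int = 256,
) -> np.ndarray:
    """Map epochs to representations h; (C, N) -> (d,) or (B, C, N) -> (B, d)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    outs = []
    for start in range(0, x.shape[0], batch_size):
        s = stft_spectrogram(
            x[start : start + batch_size].astype(np.float32), fs, spec
        )
        outs.append(encoder.forward(spectrogram_input(s)))
    h = np.concatenate(outs, axis=0)
    return h[0] if single else h


def project(h: np.ndarray, projector: nn.Sequential) -> np.ndarray:
    """Project representations to unit-norm vectors z on the hypersphere."""
    h = np.asarray(h)
    single = h.ndim == 1
    u = projector.forward(h[None] if single else h)
    z = nn.l2_normalize(u, axis=-1)
    return z[0] if single else z


def save_checkpoint(
    path,
    spec: EncoderSpec,
    encoder_params: list[np.ndarray],
    projector_params: list[np.ndarray] | None = None,
    meta: dict | None = None,
) -> None:
    """Serialize parameters plus the embedded EncoderSpec to one ``.npz`` file."""
    arrays = {f"enc_{i}": p for i, p in enumerate(encoder_params)}
    if projector_params is not None:
        arrays.update({f"proj_{i}": p for i, p in enumerate(projector_params)})
    arrays["spec_json"] = np.array(spec.to_json())
    arrays["meta_json"] = np.array(json.dumps(meta or {}))
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns (spec, encoder_params, projector_params, meta)."""
    with np.load(path, allow_pickle=False) as data:
        spec = EncoderSpec.from_json(str(data["spec_json"]))
        enc = [data[f"enc_{i}"] for i in range(sum(k.startswith("enc_") for k in data))]
        nproj = sum(k.startswith("proj_") for k in data.files)
        proj = [data[f"proj_{i}"] for i in range(nproj)] or None
        meta = json.loads(str(data["meta_json"]))
    return spec, enc, proj, meta
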