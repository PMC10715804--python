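"""Shared test utilities: toy signals, numeric gradients, a minimal EDF writer."""

from __future__ import annotations


import numpy as np


def sine_epoch(
    freq: float = 10.0, fs: float = 100.0, n: int = 1000, c: int = 4, amp: float = 1.0
) -> np.ndarray:
    """A C x N epoch whose channels all carry one pure sinusoid."""
    t = np.arange(n) / fs
    return np.tile(amp * np.sin(2 * np.pi * freq * t), (c, 1))


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f with respect to array x."""
    g = np.zeros_like(x, dtype=float)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def write_minimal_edf(path, data: np.ndarray, fs: int, channel_names: list[str]) -> None:
    """Write a bare-bones EDF file (synthetic; 1-second data records).

    Physical range is fixed at +/-1000 units against the full 16-bit digital
    range, so round-tripped amplitudes match to ~0.03 units.
    """
    c, n = data.shape
    assert n % fs == 0, "need a whole number of 1-second records"
    n_records = n // fs

    def pad(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("synthetic patient", 80),
            pad("synthetic recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (c + 1)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(c), 4),
        ]
    )
    fields = [
        (16, channel_names),
        (80, [""] * c),
        (8, ["uV"] * c),
        (8, ["-1000"] * c),
        (8, ["1000"] * c),
        (8, ["-32768"] * c),
        (8, ["32767"] * c),
        (80, [""] * c),
        (8, [str(fs)] * c),
        (32, [""] * c),
    ]
    header += b"".join(
        b"".join(pad(v, width) for v in values) for width, values in fields
    )
    scale = 32767.0 / 1000.0
    digital = np.clip(np.round(data * scale), -32768, 32767).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        for rec in range(n_records):
            for ch in range(c):
                f.write(digital[ch, rec * fs : (rec + 1) * fs].tobytes())
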