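"""File I/O: the HDF5 epoch container and optional EDF ingestion.

Container layout (one HDF5 file):

* ``signals``  — float dataset of shape (n_epochs, C, N)
* ``labels``   — optional int dataset (n_epochs,); absent means unlabeled
* ``subject``  — string dataset (n_epochs,) of subject identifiers
* attributes ``fs`` (Hz), ``channel_names``, and ``label_names`` for the
  stage coding (0=W, 1=N1, 2=N2, 3=N3, 4=R in AASM order).

EDF recordings are read through ``mne`` and segmented into disjoint
fixed-length windows; a trailing partial window is dropped.
"""

from __future__ import annotations

import numpy as np

from .epochs import EpochDataset

__all__ = ["write_epochs", "read_epochs", "read_edf", "STAGE_NAMES"]

STAGE_NAMES = ("W", "N1", "N2", "N3", "R")


def write_epochs(path, dataset: EpochDataset) -> None:
    """Write a dataset to the HDF5 container layout."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=dataset.signals.astype(np.float32))
        f.create_dataset(
            "subject",
            data=np.asarray(dataset.subjects, dtype=object),
            dtype=h5py.string_dtype(),
        )
        if dataset.labels is not None:
            f.create_dataset("labels", data=dataset.labels.astype(np.int64))
        f.attrs["fs"] = float(dataset.fs)
        f.attrs["channel_names"] = list(dataset.channel_names)
        f.attrs["label_names"] = list(STAGE_NAMES)


def read_epochs(path) -> EpochDataset:
    """Read the HDF5 container back into an :class:`EpochDataset`.

    Labels are reported absent (``None``) when the file has no ``labels``
    dataset — never silently coerced to zeros.  Validation failures name
    the offending record.
    """
    import h5py

    with h5py.File(path, "r") as f:
        if "signals" not in f or "subject" not in f:
            raise ValueError(f"{path}: missing required datasets 'signals'/'subject'")
        signals = f["signals"][...]
        if signals.ndim != 3:
            raise ValueError(
                f"{path}: 'signals' must be (n_epochs, C, N), got shape {signals.shape}"
            )
        bad = ~np.isfinite(signals).all(axis=(1, 2))
        if bad.any():
            raise ValueError(
                f"{path}: epoch {int(np.flatnonzero(bad)[0])} contains non-finite values"
            )
        subjects = np.array([s.decode() if isinstance(s, bytes) else str(s) for s in f["subject"][...]])
        labels = f["labels"][...].astype(int) if "labels" in f else None
        fs = float(f.attrs["fs"])
        channel_names = [str(c) for c in f.attrs.get("channel_names", [])]
    return EpochDataset(
        signals=signals,
        fs=fs,
        subjects=subjects,
        labels=labels,
        channel_names=channel_names,
    )


def read_edf(
    path, channel_names: list[str], epoch_seconds: float = 30.0
) -> EpochDataset:
    """Slice an EDF recording into disjoint fixed-length epochs.

    Epoch boundaries fall at exact multiples of ``epoch_seconds * fs``
    samples; the trailing partial window is dropped.  All epochs carry the
    recording's filename stem as their subject id and no labels.
    """
    import pathlib

    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)
    missing = [ch for ch in channel_names if ch not in available]
    if missing:
        raise ValueError(
            f"channels {missing} not in {path}; available channels: {available}"
        )
    raw.pick(channel_names)
    fs = float(raw.info["sfreq"])
    data = raw.get_data()  # (C, total_samples)
    samples_per_epoch = int(round(epoch_seconds * fs))
    n_epochs = data.shape[1] // samples_per_epoch
    if n_epochs == 0:
        raise ValueError(
            f"recording shorter ({data.shape[1]} samples) than one epoch "
            f"({samples_per_epoch} samples)"
        )
    trimmed = data[:, : n_epochs * samples_per_epoch]
    signals = trimmed.reshape(data.shape[0], n_epochs, samples_per_epoch).transpose(1, 0, 2)
    subject = pathlib.Path(path).stem
    return EpochDataset(
        signals=np.ascontiguousarray(signals),
        fs=fs,
        subjects=np.array([subject] * n_epochs),
        labels=None,
        channel_names=list(channel_names),
    )
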