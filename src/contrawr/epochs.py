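"""In-memory container for fixed-length multichannel signal epochs.

An *epoch* is one disjoint fixed-length window of a multichannel recording
(for sleep EEG, a 30-second window), stored as a ``C x N`` real matrix with
its sampling rate.  A dataset stacks many epochs from possibly many subjects
into an ``(n_epochs, C, N)`` array with per-epoch subject identifiers and
optional integer stage labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EpochDataset", "validate_epoch"]


def validate_epoch(data: np.ndarray, fs: float) -> np.ndarray:
    """Validate a single C x N epoch array; returns it as float
    (preserving an existing floating dtype)."""
    data = np.asarray(data)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(float)
    if data.ndim != 2:
        raise ValueError(f"epoch must be 2-D (channels x samples), got shape {data.shape}")
    c, n = data.shape
    if c < 1 or n < 2:
        raise ValueError(f"epoch needs C >= 1 channels and N >= 2 samples, got C={c}, N={n}")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got fs={fs}")
    if not np.all(np.isfinite(data)):
        raise ValueError("epoch contains non-finite values")
    return data


@dataclass
class EpochDataset:
    """A stack of equally shaped signal epochs with subject ids and labels.

    Parameters
    ----------
    signals : ndarray of shape (n_epochs, C, N)
        The raw signals, arbitrary physical units (typically microvolts).
    fs : float
        Sampling rate in Hz, shared by every epoch.
    subjects : ndarray of str, shape (n_epochs,)
        Subject identifier per epoch; splits are done at this level.
    labels : ndarray of int, shape (n_epochs,), optional
        Integer stage codes in {0..K-1}; ``None`` means unlabeled.
    channel_names : list of str, optional
        One name per channel (defaults to ch0..ch{C-1}).
    """

    signals: np.ndarray
    fs: float
    subjects: np.ndarray
    labels: np.ndarray | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)
        if self.signals.ndim != 3:
            raise ValueError(
                f"signals must be 3-D (n_epochs, C, N), got shape {self.signals.shape}"
            )
        n, c, nsamp = self.signals.shape
        if c < 1 or nsamp < 2:
            raise ValueError(f"need C >= 1 and N >= 2, got C={c}, N={nsamp}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got fs={self.fs}")
        bad = ~np.isfinite(self.signals).all(axis=(1, 2))
        if bad.any():
            raise ValueError(f"epoch {int(np.flatnonzero(bad)[0])} contains non-finite values")
        self.subjects = np.asarray(self.subjects, dtype=str)
        if self.subjects.shape != (n,):
            raise ValueError(f"subjects must have shape ({n},), got {self.subjects.shape}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError(f"labels must have shape ({n},), got {self.labels.shape}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(c)]
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )

    # -- basic protocol -------------------------------------------------

    def __len__(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def subset(self, index) -> "EpochDataset":
        """Return a new dataset restricted to the given epoch indices."""
        index = np.asarray(index)
        return EpochDataset(
            signals=self.signals[index],
            fs=self.fs,
            subjects=self.subjects[index],
            labels=None if self.labels is None else self.labels[index],
            channel_names=list(self.channel_names),
        )

    def subject_subset(self, subject_ids) -> "EpochDataset":
        """Return all epochs belonging to the given subjects."""
        wanted = set(map(str, subject_ids))
        mask = np.array([s in wanted for s in self.subjects])
        return self.subset(np.flatnonzero(mask))

    def without_labels(self) -> "EpochDataset":
        """A copy with labels stripped (the pretrain-set contract)."""
        return EpochDataset(
            signals=self.signals,
            fs=self.fs,
            subjects=self.subjects,
            labels=None,
            channel_names=list(self.channel_names),
        )

    @property
    def subject_ids(self) -> list[str]:
        """Unique subject ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(str(s), None)
        return list(seen)
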