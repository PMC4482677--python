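"""In-memory containers for continuous recordings and labeled epoch sets.

A :class:`Recording` holds a continuous multichannel signal (channels x
samples, microvolts) with its sampling rate and channel metadata.  An
:class:`EpochSet` holds fixed-length event-locked windows (epochs x channels
x samples) together with integer class labels — the unit of input to the
classifiers in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["Recording", "EpochSet", "CHANNEL_KINDS"]

CHANNEL_KINDS = ("EEG", "EMG", "OTHER")


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str
        Unique channel labels, one per row of ``data``.
    channel_kinds : sequence of str
        Per-channel tag, one of ``"EEG"``, ``"EMG"``, ``"OTHER"``.
    start_time : float
        Time of the first sample in seconds (default 0).
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    channel_kinds: Sequence[str] | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.channel_kinds is None:
            self.channel_kinds = ["EEG"] * len(self.channel_names)
        self.channel_kinds = [str(k).upper() for k in self.channel_kinds]
        if len(self.channel_kinds) != len(self.channel_names):
            raise ValueError("channel_kinds length mismatch")
        for k in self.channel_kinds:
            if k not in CHANNEL_KINDS:
                raise ValueError(f"unknown channel kind {k!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs

    def pick(self, kind: str) -> "Recording":
        """Return a sub-recording containing only channels of one kind."""
        kind = kind.upper()
        idx = [i for i, k in enumerate(self.channel_kinds) if k == kind]
        if not idx:
            raise ValueError(f"recording has no {kind} channels")
        return Recording(
            data=self.data[idx],
            fs=self.fs,
            channel_names=[self.channel_names[i] for i in idx],
            channel_kinds=[self.channel_kinds[i] for i in idx],
            start_time=self.start_time,
        )

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class EpochSet:
    """Labeled fixed-length epochs (epochs x channels x samples)."""

    epochs: np.ndarray
    labels: np.ndarray
    class_names: Sequence[str]
    fs: float
    window: tuple[float, float]
    channel_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x samples)")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("one label per epoch required")
        self.class_names = list(self.class_names)
        n_classes = len(self.class_names)
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= n_classes
        ):
            raise ValueError("labels must lie in [0, n_classes)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.window = (float(self.window[0]), float(self.window[1]))
        expected = int(round((self.window[0] + self.window[1]) * self.fs))
        if self.epochs.shape[0] and self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} inconsistent with "
                f"window {self.window} at fs={self.fs} (expected {expected})"
            )
        self.channel_names = list(self.channel_names)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.epochs.shape[1])]
        if len(self.channel_names) != self.epochs.shape[1]:
            raise ValueError("channel_names length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def input_dim(self) -> int:
        """Width of one flattened epoch (channels x samples)."""
        return self.n_channels * self.n_samples

    def flatten(self) -> np.ndarray:
        """Flatten epochs to rows, channel-major.

        Row layout is channel 0's samples, then channel 1's, ... — the fixed
        input convention of every network in this package.
        """
        return self.epochs.reshape(self.n_epochs, -1)

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            epochs=self.epochs[idx],
            labels=self.labels[idx],
            class_names=list(self.class_names),
            fs=self.fs,
            window=self.window,
            channel_names=list(self.channel_names),
        )

    def __eq__(self, other) -> bool:  # lossless round-trip comparisons
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            np.array_equal(self.epochs, other.epochs)
            and np.array_equal(self.labels, other.labels)
            and self.class_names == other.class_names
            and self.fs == other.fs
            and self.window == other.window
            and self.channel_names == other.channel_names
        )
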