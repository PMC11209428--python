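"""Core containers for continuous recordings, event series, and epoch sets.

All amplitudes are in microvolts (µV), all times in seconds from recording
start, and sample index = round(t * fs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: EEG montage used throughout: 11 channels of the 10-20 system.
EEG_CHANNELS = ("FP1", "F3", "Fz", "F4", "FCz", "C3", "Cz", "C4", "P3", "Pz", "P4")
EMG_CHANNEL = "EMG"

DEFAULT_FS = 500.0


@dataclass
class ContinuousRecording:
    """Multichannel continuous time series in µV.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Per-channel sample arrays in µV.
    fs : float
        Sampling rate in Hz (default 500).
    channel_labels : tuple of str
        Ordered, unique channel names (10-20 labels for EEG, "EMG" for the
        bipolar channel).
    start_offset : float
        Offset of the first sample in seconds (normally 0).
    """

    data: np.ndarray
    fs: float = DEFAULT_FS
    channel_labels: tuple = EEG_CHANNELS
    start_offset: float = 0.0

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[1] == 0:
            raise ValueError("recording has zero samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError(f"duplicate channel labels in {self.channel_labels}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the sample array of one channel by label."""
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording ({', '.join(self.channel_labels)})"
            ) from None
        return self.data[i]

    def pick(self, labels) -> "ContinuousRecording":
        """Sub-recording containing only `labels`, in the given order."""
        idx = [self.channel_labels.index(l) if l in self.channel_labels else -1 for l in labels]
        missing = [l for l, i in zip(labels, idx) if i < 0]
        if missing:
            raise KeyError(f"missing channels: {missing}")
        return ContinuousRecording(
            self.data[idx], self.fs, tuple(labels), self.start_offset
        )


@dataclass
class EventSeries:
    """Strictly increasing event times in seconds from recording start."""

    onset_times: np.ndarray
    source: str = "ground-truth"  # or "emg-detected"

    def __post_init__(self):
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        if self.onset_times.ndim != 1:
            raise ValueError("onset_times must be 1-D")
        if len(self.onset_times) > 1 and not np.all(np.diff(self.onset_times) > 0):
            raise ValueError("onset times must be strictly increasing")

    def __len__(self):
        return len(self.onset_times)


@dataclass
class EpochSet:
    """Stacked fixed-length windows: epoch x channel x sample.

    The relative time axis ``t`` is uniform with step 1/fs.  Epoch windows
    are half-open on the right, [t0, t1), so a 2-s epoch at 500 Hz holds
    exactly 1000 samples; measurement windows inside an epoch follow the
    same convention except the motor-potential window, which is closed.
    """

    epochs: np.ndarray
    t: np.ndarray
    fs: float
    channel_labels: tuple
    labels: np.ndarray = None  # class per epoch: "mrcp" | "idle"
    kept_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim == 2:  # single channel convenience
            self.epochs = self.epochs[:, None, :]
        self.t = np.asarray(self.t, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.epochs.shape[2] != len(self.t):
            raise ValueError("time axis length does not match epoch samples")
        if len(self.t) > 1:
            steps = np.diff(self.t)
            if not np.allclose(steps, 1.0 / self.fs, rtol=0, atol=1e-9):
                raise ValueError("time axis must be uniform with step 1/fs")
        if self.labels is None:
            self.labels = np.array(["mrcp"] * self.epochs.shape[0])
        else:
            self.labels = np.asarray(self.labels)
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("one label per epoch required")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.epochs.shape[0], dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def kept(self) -> "EpochSet":
        """Subset of epochs that survived artifact rejection."""
        m = self.kept_mask
        return EpochSet(
            self.epochs[m], self.t, self.fs, self.channel_labels,
            labels=self.labels[m],
        )

    def channel(self, label: str) -> np.ndarray:
        i = self.channel_labels.index(label)
        return self.epochs[:, i, :]


def window_slice(t: np.ndarray, lo: float, hi: float, closed: bool = False) -> np.ndarray:
    """Boolean mask for samples with lo <= t < hi (or <= hi when closed).

    A half-sample tolerance absorbs floating-point fuzz on the time grid.
    """
    dt = t[1] - t[0] if len(t) > 1 else 1e-9
    eps = dt / 2
    if closed:
        return (t >= lo - eps) & (t <= hi + eps)
    return (t >= lo - eps) & (t < hi - eps)
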