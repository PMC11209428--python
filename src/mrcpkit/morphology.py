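"""MRCP morphology: averaged waveforms and RP/NS/MP component amplitudes.

The continuous EEG is bandpass filtered (0.1-10 Hz, order 4, zero-phase)
before epoching — never per epoch, to keep filter transients out of the
epochs.  Three-second epochs (-2 to +1 s around each movement onset) are
extracted, epochs with any sample beyond ±125 µV on any channel are
rejected, the survivors are averaged, and the component amplitudes are the
window means of the average:

* RP (readiness potential):  [-2, -0.5) s
* NS (negative slope):       [-0.5, -0.1) s
* MP (motor potential):      [-0.1, +0.1] s (closed)

Components are reported for Fz, FCz, and Cz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ContinuousRecording, EventSeries, EpochSet, window_slice
from .filters import bandpass_recording
from .synth import MRCP_WINDOWS

log = logging.getLogger(__name__)

MORPHOLOGY_BAND = (0.1, 10.0)
MORPHOLOGY_WINDOW = (-2.0, 1.0)
ARTIFACT_LIMIT = 125.0  # µV, strict inequality
COMPONENT_CHANNELS = ("Fz", "FCz", "Cz")


def preprocess_morphology(eeg: ContinuousRecording) -> ContinuousRecording:
    """0.1-10 Hz order-4 zero-phase Butterworth on every channel."""
    return bandpass_recording(eeg, *MORPHOLOGY_BAND, order=4)


def extract_epochs(
    eeg: ContinuousRecording,
    onsets: EventSeries,
    window: tuple = MORPHOLOGY_WINDOW,
    label: str = "mrcp",
) -> EpochSet:
    """Fixed-length epochs around onsets; window is half-open on the right.

    Onsets without full pre/post context are skipped (count logged).
    A (-2, +1) window at 500 Hz yields exactly 1500 samples per epoch.
    """
    fs = eeg.fs
    a = int(round(window[0] * fs))
    b = int(round(window[1] * fs))
    n = eeg.n_samples
    idx = np.round(np.asarray(onsets.onset_times) * fs).astype(int)
    usable = (idx + a >= 0) & (idx + b <= n)
    skipped = int((~usable).sum())
    if skipped:
        log.info("extract_epochs: skipped %d onset(s) lacking context", skipped)
    if not usable.any():
        raise ValueError("no onset has full epoch context within the recording")
    epochs = np.stack([eeg.data[:, i + a : i + b] for i in idx[usable]])
    t = np.arange(a, b) / fs
    return EpochSet(
        epochs, t, fs, eeg.channel_labels,
        labels=np.array([label] * epochs.shape[0]),
    )


def reject_artifacts(epochs: EpochSet, limit: float = ARTIFACT_LIMIT) -> EpochSet:
    """Flag epochs containing any sample with |v| > limit on any channel.

    The comparison is strict: a sample at exactly ±limit is kept.  The scan
    covers every channel present in the epoch set, so the morphology stage
    (all 11 EEG channels) and the detection stage (surrogate channel only)
    each apply it to their own channel set.
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    peak = np.max(np.abs(epochs.epochs), axis=(1, 2))
    kept = peak <= limit
    if not kept.any():
        raise ValueError(
            f"all {epochs.n_epochs} epochs exceed ±{limit} µV "
            f"(peak range {peak.min():.1f}-{peak.max():.1f} µV)"
        )
    n_rej = int((~kept).sum())
    if n_rej:
        log.info("reject_artifacts: rejected %d of %d epochs", n_rej, epochs.n_epochs)
    return EpochSet(
        epochs.epochs, epochs.t, epochs.fs, epochs.channel_labels,
        labels=epochs.labels, kept_mask=kept,
    )


def average_mrcp(epochs: EpochSet):
    """Pointwise mean (and standard error) over kept epochs.

    Returns (mean, se), each of shape (n_channels, n_samples).  With a
    single kept epoch the SE is zero by convention (flagged in the log).
    """
    kept = epochs.kept()
    if kept.n_epochs == 0:
        raise ValueError("no kept epochs to average")
    mean = kept.epochs.mean(axis=0)
    if kept.n_epochs == 1:
        log.info("average_mrcp: single epoch; SE set to 0 by convention")
        se = np.zeros_like(mean)
    else:
        se = kept.epochs.std(axis=0, ddof=1) / np.sqrt(kept.n_epochs)
    return mean, se


@dataclass
class ComponentAmplitudes:
    """RP/NS/MP mean amplitudes (µV) per channel for one session."""

    values: dict            # (channel, component) -> µV
    n_epochs_kept: int
    n_epochs_rejected: int

    def to_frame(self, session: str = "") -> pd.DataFrame:
        rows = [
            {"channel": ch, "component": comp, "session": session, "amplitude_uV": v}
            for (ch, comp), v in self.values.items()
        ]
        return pd.DataFrame(rows)


def component_amplitudes(
    avg: np.ndarray,
    t: np.ndarray,
    channel_labels,
    channels=COMPONENT_CHANNELS,
    n_kept: int = 0,
    n_rejected: int = 0,
) -> ComponentAmplitudes:
    """Window means of the average waveform on the requested channels."""
    if t[0] > MRCP_WINDOWS["RP"][0] or t[-1] < MRCP_WINDOWS["MP"][1]:
        raise ValueError("average waveform must cover [-2, +0.1] s")
    labels = list(channel_labels)
    values = {}
    for ch in channels:
        if ch not in labels:
            raise KeyError(f"channel {ch!r} absent from the average")
        w = avg[labels.index(ch)]
        for comp, (lo, hi, closed) in MRCP_WINDOWS.items():
            m = window_slice(t, lo, hi, closed)
            values[(ch, comp)] = float(w[m].mean())
    return ComponentAmplitudes(values, n_kept, n_rejected)


def session_morphology(
    eeg: ContinuousRecording, onsets: EventSeries
) -> ComponentAmplitudes:
    """Full morphology stage: filter, epoch, reject, average, measure."""
    filt = preprocess_morphology(eeg)
    epochs = reject_artifacts(extract_epochs(filt, onsets))
    avg, _ = average_mrcp(epochs)
    kept = int(epochs.kept_mask.sum())
    return component_amplitudes(
        avg, epochs.t, epochs.channel_labels,
        n_kept=kept, n_rejected=epochs.n_epochs - kept,
    )
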