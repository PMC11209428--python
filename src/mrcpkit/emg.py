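"""Movement-onset detection from the bipolar EMG channel.

Pipeline: 20-40 Hz order-4 zero-phase Butterworth bandpass, full-wave
rectification, then threshold crossing with a refractory period.  The
detection threshold is either supplied explicitly (the participant-specific
approach) or derived from a quiet baseline at the start of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EventSeries
from .filters import bandpass_zero_phase


@dataclass
class OnsetDetectionParams:
    """Parameters of the EMG onset detector.

    ``threshold`` is in µV on the rectified, bandpassed signal; ``refractory``
    is the minimum gap between consecutive detections in seconds (movements
    are self-paced roughly every 10 s, so 5 s suppresses within-burst
    re-triggering without masking real movements).
    """

    band: tuple = (20.0, 40.0)
    filter_order: int = 4
    threshold: float | None = None  # µV; None -> use auto_threshold
    refractory: float = 5.0         # s

    def __post_init__(self):
        if self.refractory <= 0:
            raise ValueError("refractory period must be positive")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be positive")


def preprocess_emg(emg: np.ndarray, fs: float, params: OnsetDetectionParams) -> np.ndarray:
    """Bandpassed and full-wave rectified EMG."""
    return np.abs(
        bandpass_zero_phase(emg, params.band[0], params.band[1], fs, params.filter_order)
    )


def auto_threshold(
    emg: np.ndarray, fs: float, params: OnsetDetectionParams | None = None,
    baseline_duration: float = 10.0, n_sd: float = 8.0,
) -> float:
    """Detection threshold from a burst-free baseline at the recording start.

    threshold = mean + `n_sd` * SD of the rectified, filtered signal over
    the first `baseline_duration` seconds.  The default multiplier of 8 is
    chosen so that threshold crossings of burst-free 20-40 Hz noise are
    vanishingly rare over a whole session (by Rice's formula a mean+5·SD
    threshold is crossed about twice per 100 s at this bandwidth, which
    would corrupt the onset count); bursts sit far above either value.

    The segment must be quiet: if its amplitude statistics are inflated by
    bursts the resulting threshold will not separate movements, so a
    baseline whose maximum dwarfs the candidate threshold is rejected.
    """
    params = params or OnsetDetectionParams()
    nb = int(round(baseline_duration * fs))
    if len(emg) < nb:
        raise ValueError(
            f"recording shorter ({len(emg)/fs:.1f} s) than the required "
            f"{baseline_duration:.0f} s baseline"
        )
    rect = preprocess_emg(np.asarray(emg, dtype=float), fs, params)
    base = rect[:nb]
    thr = base.mean() + n_sd * base.std()
    if thr <= 0:
        raise ValueError("baseline is constant (zero variance); cannot derive a threshold")
    # burst-like activity inflates the SD far beyond the robust (MAD) scale
    robust_sd = 1.4826 * np.median(np.abs(base - np.median(base)))
    if robust_sd > 0 and base.std() > 3 * robust_sd:
        raise ValueError(
            "no quiet baseline at the recording start (burst-like activity present)"
        )
    return float(thr)


def detect_onsets(
    emg: np.ndarray, fs: float, params: OnsetDetectionParams | None = None
) -> EventSeries:
    """Detect movement onsets as threshold crossings of the rectified EMG.

    An onset is the first sample whose rectified amplitude exceeds the
    threshold; subsequent crossings within the refractory period are
    suppressed.  Returns times in seconds from recording start.
    """
    params = params or OnsetDetectionParams()
    emg = np.asarray(emg, dtype=float)
    thr = params.threshold
    if thr is None:
        thr = auto_threshold(emg, fs, params)
    rect = preprocess_emg(emg, fs, params)
    above = np.flatnonzero(rect > thr)
    gap = int(round(params.refractory * fs))
    # keep crossings at least `gap` samples after the last kept one
    kept = []
    for i in above:
        if not kept or i - kept[-1] >= gap:
            kept.append(i)
    return EventSeries(np.asarray(kept, dtype=float) / fs, source="emg-detected")


def interval_outliers(onsets: EventSeries, expected_interval: float = 10.0,
                      tolerance: float = 2.0) -> np.ndarray:
    """Indices of inter-onset intervals deviating > `tolerance` s from the
    expected pacing — the automated stand-in for a manual plausibility check
    of the detected movements."""
    iv = np.diff(onsets.onset_times)
    return np.flatnonzero(np.abs(iv - expected_interval) > tolerance)
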