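"""Zero-phase Butterworth filtering shared by the EMG, morphology, and
detection stages.

"Order" always refers to the overall filter order: an order-4 bandpass is
designed as a 2nd-order Butterworth prototype (scipy doubles the order for
bandpass designs).  Filters are applied forward-backward (``sosfiltfilt``),
so the effective magnitude response is |H(f)|^2 and the phase response is
identically zero.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .data import ContinuousRecording

log = logging.getLogger(__name__)


def design_bandpass(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    """Second-order sections of an order-`order` Butterworth bandpass."""
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for fs={fs} Hz (need 0 < low < high < fs/2)"
        )
    if order < 2 or order % 2:
        raise ValueError(f"overall bandpass order must be even and >= 2, got {order}")
    sos = signal.butter(order // 2, [low, high], btype="bandpass", fs=fs, output="sos")
    log.debug("butterworth bandpass %.3g-%.3g Hz order %d at fs=%g: sos=%s",
              low, high, order, fs, sos.tolist())
    return sos


def bandpass_magnitude(f, low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    """|H(f)|^2 of the forward-backward filter at frequencies `f` (Hz).

    This is the amplitude ratio a sinusoid at `f` experiences after
    zero-phase filtering, and serves as the analytic oracle for the
    filtering contract.
    """
    sos = design_bandpass(low, high, fs, order)
    w, h = signal.sosfreqz(sos, worN=2 * np.pi * np.atleast_1d(f) / fs)
    return np.abs(h) ** 2


def bandpass_zero_phase(
    x: np.ndarray, low: float, high: float, fs: float, order: int = 4
) -> np.ndarray:
    """Forward-backward Butterworth bandpass of a 1-D signal.

    Output has the same length as the input and zero phase distortion
    (a symmetric pulse keeps its peak sample).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("bandpass_zero_phase expects a 1-D signal")
    sos = design_bandpass(low, high, fs, order)
    # sosfiltfilt pads with ~3x the IIR settling length; reject signals too
    # short to pad rather than silently producing garbage.
    ntaps = max(len(signal.sos2tf(sos)[0]), len(signal.sos2tf(sos)[1]))
    if len(x) <= 3 * ntaps:
        raise ValueError(f"signal too short ({len(x)} samples) to zero-phase filter")
    return signal.sosfiltfilt(sos, x)


def bandpass_recording(
    rec: ContinuousRecording, low: float, high: float, order: int = 4
) -> ContinuousRecording:
    """Apply the same zero-phase bandpass to every channel of a recording."""
    out = np.vstack([bandpass_zero_phase(ch, low, high, rec.fs, order) for ch in rec.data])
    return ContinuousRecording(out, rec.fs, rec.channel_labels, rec.start_offset)
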