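"""Denoising applied before any transform.

Each taxel's time series is low-pass filtered independently with a
second-order IIR filter whose pass-band edge is a fixed fraction of the
sampling rate (fs/7 by default).  The filter family is Butterworth
(maximally flat, the least-surprising second-order IIR low-pass) and the
default application is zero-phase forward-backward filtering, so temporal
error comparisons downstream are not biased by phase lag.  A causal
single-pass variant is available as a switch because either reading of the
procedure is defensible.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .errors import ValidationError
from .io import TactileRecording


def butter_lowpass(order: int = 2, cutoff_fraction: float = 1.0 / 7.0):
    """Design the denoising filter; returns (b, a).

    ``cutoff_fraction`` is the pass-band edge as a fraction of the sampling
    rate, so the normalized scipy cutoff (fraction of Nyquist) is twice it.
    """
    if not 0 < cutoff_fraction < 0.5:
        raise ValidationError("cutoff_fraction: must lie in (0, 0.5)")
    if order < 1:
        raise ValidationError("order: must be >= 1")
    return scipy.signal.butter(order, 2.0 * cutoff_fraction, btype="low")


def lowpass_denoise(
    rec: TactileRecording,
    order: int = 2,
    cutoff_fraction: float = 1.0 / 7.0,
    causal: bool = False,
) -> TactileRecording:
    """Low-pass denoise a recording along time; shape unchanged.

    Output frames are real-valued (no re-quantization).  ``causal=True``
    uses a single forward pass (phase lag included); the default filters
    forward-backward for zero phase.
    """
    b, a = butter_lowpass(order=order, cutoff_fraction=cutoff_fraction)
    warmup = 3 * max(len(a), len(b))
    if rec.n_frames <= warmup:
        raise ValidationError(
            f"frames: recording length {rec.n_frames} is shorter than the "
            f"filter warm-up length {warmup}"
        )
    x = rec.frames.astype(float)
    if causal:
        y = scipy.signal.lfilter(b, a, x, axis=0)
    else:
        y = scipy.signal.filtfilt(b, a, x, axis=0)
    meta = dict(rec.metadata)
    meta["denoised"] = f"butterworth(order={order}, cutoff=fs*{cutoff_fraction:g}, causal={causal})"
    return rec.copy_with(frames=y, metadata=meta)


def magnitude_response(order: int, cutoff_fraction: float, freq_fractions) -> np.ndarray:
    """|H| of the designed filter at frequencies given as fractions of fs."""
    b, a = butter_lowpass(order=order, cutoff_fraction=cutoff_fraction)
    w = 2.0 * np.pi * np.asarray(freq_fractions, dtype=float)
    _, h = scipy.signal.freqz(b, a, worN=w)
    return np.abs(h)
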