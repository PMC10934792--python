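"""Per-trial, per-channel preprocessing for epoched EEG.

The chain mirrors standard motor-imagery practice: mains notch, broad
band-pass (1-50 Hz), anti-aliased downsampling, epoch time-cropping and
baseline correction.  All operations are label-agnostic and act
independently on each trial and channel.

Filtering uses 4th-order Butterworth sections applied forward-backward
(zero phase); the notch is a second-order IIR band-stop with quality
factor 30.  Time is in seconds with half-open windows ``[start, end)``
and sample index ``round_half_away((t - t0) * sfreq)``.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .io_fixture import EpochSet

__all__ = [
    "bandpass",
    "lowpass",
    "notch",
    "resample",
    "crop_time",
    "baseline_correct",
]

BUTTER_ORDER = 4
NOTCH_Q = 30.0


def _round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1, -0.5 -> -1)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def _sample_index(t: float, t0: float, sfreq: float) -> int:
    return _round_half_away((t - t0) * sfreq)


def bandpass(epochs: EpochSet, lo: float, hi: float, order: int = BUTTER_ORDER) -> EpochSet:
    """Zero-phase Butterworth band-pass of every trial and channel."""
    nyq = epochs.sfreq / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"band edges must satisfy 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(f"upper band edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=epochs.sfreq, output="sos")
    out = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(out, epochs.labels, epochs.sfreq, list(epochs.channel_names), epochs.t0)


def lowpass(epochs: EpochSet, hi: float, order: int = BUTTER_ORDER) -> EpochSet:
    """Zero-phase Butterworth low-pass (used before aggressive decimation)."""
    nyq = epochs.sfreq / 2.0
    if not (0 < hi < nyq):
        raise ValueError(f"cutoff must be in (0, Nyquist={nyq}), got {hi}")
    sos = signal.butter(order, hi, btype="lowpass", fs=epochs.sfreq, output="sos")
    out = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(out, epochs.labels, epochs.sfreq, list(epochs.channel_names), epochs.t0)


def notch(epochs: EpochSet, mains: float = 50.0, q: float = NOTCH_Q) -> EpochSet:
    """Narrow zero-phase band-stop at the mains frequency."""
    nyq = epochs.sfreq / 2.0
    if not (0 < mains < nyq):
        raise ValueError(f"mains frequency {mains} Hz must be below Nyquist {nyq} Hz")
    b, a = signal.iirnotch(mains, q, fs=epochs.sfreq)
    out = signal.filtfilt(b, a, epochs.data, axis=-1)
    return EpochSet(out, epochs.labels, epochs.sfreq, list(epochs.channel_names), epochs.t0)


def resample(epochs: EpochSet, target_sfreq: float, allow_upsample: bool = False) -> EpochSet:
    """Polyphase FIR anti-aliased resampling to ``target_sfreq``.

    The rate change is realized as the rational approximation
    ``target/original`` (denominator <= 1000); ``t0`` is preserved because
    the first sample's instant is unchanged by polyphase resampling.
    """
    if target_sfreq <= 0:
        raise ValueError("target_sfreq must be positive")
    if target_sfreq > epochs.sfreq and not allow_upsample:
        raise ValueError(
            f"upsampling {epochs.sfreq} -> {target_sfreq} Hz requested but not allowed"
        )
    if np.isclose(target_sfreq, epochs.sfreq):
        return epochs.copy()
    frac = Fraction(target_sfreq / epochs.sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(epochs.data, up, down, axis=-1)
    new_sfreq = epochs.sfreq * up / down
    return EpochSet(out, epochs.labels, new_sfreq, list(epochs.channel_names), epochs.t0)


def crop_time(epochs: EpochSet, start: float, end: float) -> EpochSet:
    """Restrict the sample axis to the half-open window ``[start, end)``.

    Times are on the epoch's own axis (seconds relative to task onset);
    ``t0`` of the result is the time of its first retained sample.
    """
    if end <= start:
        raise ValueError(f"empty crop window [{start}, {end})")
    i0 = _sample_index(start, epochs.t0, epochs.sfreq)
    i1 = _sample_index(end, epochs.t0, epochs.sfreq)
    i0 = max(i0, 0)
    i1 = min(i1, epochs.n_samples)
    if i1 <= i0:
        raise ValueError(
            f"crop window [{start}, {end}) s contains no samples of the epoch "
            f"(t0={epochs.t0}, duration={epochs.n_samples / epochs.sfreq} s)"
        )
    out = epochs.data[:, :, i0:i1]
    new_t0 = epochs.t0 + i0 / epochs.sfreq
    return EpochSet(out, epochs.labels, epochs.sfreq, list(epochs.channel_names), new_t0)


def baseline_correct(epochs: EpochSet, window) -> EpochSet:
    """Subtract the mean over ``window=[start, end)`` from each trial/channel."""
    start, end = window
    if end <= start:
        raise ValueError(f"empty baseline window [{start}, {end})")
    i0 = max(_sample_index(start, epochs.t0, epochs.sfreq), 0)
    i1 = min(_sample_index(end, epochs.t0, epochs.sfreq), epochs.n_samples)
    if i1 <= i0:
        raise ValueError(f"baseline window [{start}, {end}) s contains no samples")
    base = epochs.data[:, :, i0:i1].mean(axis=-1, keepdims=True)
    return EpochSet(
        epochs.data - base, epochs.labels, epochs.sfreq, list(epochs.channel_names), epochs.t0
    )
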