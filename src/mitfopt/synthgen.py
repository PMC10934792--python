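"""Synthetic two-class motor-imagery EEG with planted ERD.

Each trial is independent 1/f^gamma background noise per channel plus a
narrow-band oscillation (the "sensorimotor rhythm") present on all
channels for the whole trial.  Event-related desynchronization (ERD) is
modeled as amplitude attenuation of that oscillation: during the planted
time window only, on the informative channels of a trial's class, the
oscillation amplitude is scaled by ``sqrt(1 - erd_depth)``.  Because ERD
is a power phenomenon, attenuating a non-phase-locked oscillation is the
minimal faithful model; no ERS rebound is simulated.

The attenuation envelope is smoothed with a 100 ms raised-cosine ramp so
the window edges do not create broadband transients that would trivially
cue the time window.

An optional common-mode component (a band-limited oscillation shared by a
chosen channel subset for the entire trial) supports stress-testing the
correlation-based channel selector, which looks for channel groups
carrying shared signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .io_fixture import EpochSet
from .tfsegment import TimeFreqSegment

__all__ = ["SynthParams", "generate", "band_power"]

RAMP_S = 0.1  # raised-cosine ramp length of the ERD envelope, seconds


@dataclass
class SynthParams:
    """Generator settings; defaults define the reference study conditions.

    ``oscillation_scale`` is the RMS amplitude (microvolts) of the
    band-limited rhythm relative to ``background_scale`` (RMS of the 1/f
    background).  The default 0.7 gives a moderate in-band SNR typical of
    a clear sensorimotor rhythm at the scalp: a correctly placed
    time-frequency segment decodes at ~95% or better, while mis-placed
    segments (wrong band, or a window diluted by non-task time) lose tens
    of accuracy points, so the segment search has a real gradient.
    """

    n_trials_per_class: int = 100
    n_channels: int = 16
    sfreq: float = 125.0
    trial_length: float = 4.0
    t0: float = 0.0
    planted_segment: TimeFreqSegment = field(
        default_factory=lambda: TimeFreqSegment(fstart=9.0, fwidth=4.0, tstart=0.5, twidth=2.0)
    )
    informative_channels: Mapping[int, Sequence[int]] = field(
        default_factory=lambda: {0: (2, 3)}
    )
    erd_depth: float = 0.8
    background_scale: float = 1.0
    oscillation_scale: float = 0.7
    noise_exponent: float = 1.0
    common_channels: Optional[Sequence[int]] = None
    common_scale: float = 1.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_length * self.sfreq))

    def validate(self) -> None:
        seg = self.planted_segment
        nyq = self.sfreq / 2.0
        if not (self.n_trials_per_class >= 1 and self.n_channels >= 1):
            raise ValueError("trial and channel counts must be positive")
        if seg.fstop >= nyq:
            raise ValueError(f"planted band edge {seg.fstop} Hz >= Nyquist {nyq} Hz")
        if seg.fstart <= 0 or seg.fwidth <= 0 or seg.twidth <= 0:
            raise ValueError("planted segment must have positive band and window")
        t_end = self.t0 + self.trial_length
        if seg.tstart < self.t0 - 1e-9 or seg.tstop > t_end + 1e-9:
            raise ValueError(
                f"planted window [{seg.tstart}, {seg.tstop}] s outside trial "
                f"extent [{self.t0}, {t_end}] s"
            )
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must be in [0, 1]")
        for cls, chans in self.informative_channels.items():
            if any(not (0 <= c < self.n_channels) for c in chans):
                raise ValueError(f"informative channels for class {cls} out of range")
        if self.common_channels is not None and any(
            not (0 <= c < self.n_channels) for c in self.common_channels
        ):
            raise ValueError("common_channels out of range")


def _pink_noise(rng: np.random.Generator, shape, sfreq: float, exponent: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise, unit RMS."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / sfreq)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=shape[-1], axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _narrowband_noise(
    rng: np.random.Generator, shape, sfreq: float, lo: float, hi: float
) -> np.ndarray:
    """Band-limited Gaussian noise (brick-wall spectral mask), unit RMS."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / sfreq)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] Hz contains no FFT bins at sfreq {sfreq}")
    x = np.fft.irfft(spec * mask, n=shape[-1], axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _erd_envelope(params: SynthParams) -> np.ndarray:
    """Amplitude envelope: 1 outside the window, sqrt(1-depth) inside.

    Transitions are raised-cosine ramps of RAMP_S seconds placed inside the
    window, so the attenuation never leaks outside the planted interval.
    """
    n = params.n_samples
    t = params.t0 + np.arange(n) / params.sfreq
    seg = params.planted_segment
    lo_amp = float(np.sqrt(1.0 - params.erd_depth))
    ramp = min(RAMP_S, seg.twidth / 2.0)
    depth_profile = np.zeros(n)  # 0 -> no attenuation, 1 -> full attenuation
    inside = (t >= seg.tstart) & (t < seg.tstop)
    depth_profile[inside] = 1.0
    if ramp > 0:
        rising = inside & (t < seg.tstart + ramp)
        depth_profile[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - seg.tstart) / ramp))
        falling = inside & (t >= seg.tstop - ramp)
        depth_profile[falling] = 0.5 * (1 - np.cos(np.pi * (seg.tstop - t[falling]) / ramp))
    return 1.0 + (lo_amp - 1.0) * depth_profile


def generate(params: SynthParams) -> EpochSet:
    """Generate a balanced two-class :class:`EpochSet`; deterministic per seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_per = params.n_trials_per_class
    n_trials = 2 * n_per
    C, S = params.n_channels, params.n_samples
    seg = params.planted_segment

    labels = np.tile([0, 1], n_per)  # interleaved, exactly balanced
    envelope = _erd_envelope(params)

    data = np.empty((n_trials, C, S))
    for tr in range(n_trials):
        cls = int(labels[tr])
        bg = params.background_scale * _pink_noise(rng, (C, S), params.sfreq, params.noise_exponent)
        osc = params.oscillation_scale * _narrowband_noise(
            rng, (C, S), params.sfreq, seg.fstart, seg.fstop
        )
        amp = np.ones((C, S))
        for ch in params.informative_channels.get(cls, ()):
            amp[ch] = envelope
        trial = bg + amp * osc
        if params.common_channels is not None:
            shared = params.common_scale * _narrowband_noise(
                rng, (S,), params.sfreq, seg.fstart, seg.fstop
            )
            trial[list(params.common_channels)] += shared
        data[tr] = trial

    names = [f"CH{i:02d}" for i in range(C)]
    epochs = EpochSet(data=data, labels=labels, sfreq=params.sfreq, channel_names=names, t0=params.t0)
    epochs.validate()
    return epochs


def band_power(epochs: EpochSet, segment: TimeFreqSegment, channels: Sequence[int]) -> np.ndarray:
    """Per-trial mean squared amplitude in a time-frequency segment.

    Band-pass the whole trial (4th-order zero-phase Butterworth), crop to
    the segment's time window, then average the squared signal over samples
    and over the given channels.  Serves as an independent oracle for the
    planted power structure; it shares no code with the decoding pipeline's
    feature path.
    """
    channels = list(channels)
    if not channels:
        raise ValueError("channel set must be non-empty")
    nyq = epochs.sfreq / 2.0
    if segment.fstop >= nyq:
        raise ValueError(f"band edge {segment.fstop} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(4, [segment.fstart, segment.fstop], btype="bandpass", fs=epochs.sfreq, output="sos")
    filtered = sps.sosfiltfilt(sos, epochs.data[:, channels, :], axis=-1)
    i0 = max(int(round((segment.tstart - epochs.t0) * epochs.sfreq)), 0)
    i1 = min(int(round((segment.tstop - epochs.t0) * epochs.sfreq)), epochs.n_samples)
    if i1 <= i0:
        raise ValueError("segment time window contains no samples")
    windowed = filtered[:, :, i0:i1]
    return (windowed**2).mean(axis=(1, 2))
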