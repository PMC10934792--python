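"""Time-frequency segments: the search space of the segment optimizer.

A segment is a rectangle in the time-frequency plane — a time window
``[tstart, tstart + twidth)`` (seconds, relative to task onset) crossed with
a frequency band ``[fstart, fstart + fwidth]`` (Hz).  The optimizer searches
over segments in normalized ``[0, 1]^4`` coordinates; :func:`decode_position`
maps any point of the unit box onto a valid segment, so no candidate is ever
rejected.  :func:`apply_segment` restricts an epoch set to a segment by
cropping in time and band-filtering in frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "TimeFreqSegment",
    "SearchBounds",
    "decode_position",
    "apply_segment",
    "interval_jaccard",
]


@dataclass(frozen=True)
class TimeFreqSegment:
    """A time window x frequency band rectangle.

    Parameters are the start/width encoding used by the optimizer: a
    4-vector (fstart, fwidth, tstart, twidth) with frequencies in Hz and
    times in seconds relative to task onset.
    """

    fstart: float
    fwidth: float
    tstart: float
    twidth: float

    @property
    def fstop(self) -> float:
        return self.fstart + self.fwidth

    @property
    def tstop(self) -> float:
        return self.tstart + self.twidth

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TimeFreqSegment":
        return cls(
            fstart=float(d["fstart"]),
            fwidth=float(d["fwidth"]),
            tstart=float(d["tstart"]),
            twidth=float(d["twidth"]),
        )

    def validate(self, bounds: "SearchBounds") -> None:
        b = bounds
        if not (self.fwidth >= b.min_fwidth > 0):
            raise ValueError(f"fwidth {self.fwidth} below minimum {b.min_fwidth}")
        if not (self.twidth >= b.min_twidth > 0):
            raise ValueError(f"twidth {self.twidth} below minimum {b.min_twidth}")
        if self.fstart < b.fmin or self.fstop > b.fmax + 1e-9:
            raise ValueError(f"frequency band [{self.fstart}, {self.fstop}] outside [{b.fmin}, {b.fmax}]")
        if self.tstart < b.tmin or self.tstop > b.tmax + 1e-9:
            raise ValueError(f"time window [{self.tstart}, {self.tstop}] outside [{b.tmin}, {b.tmax}]")


@dataclass(frozen=True)
class SearchBounds:
    """Box constraints of the segment search.

    Defaults: time window anywhere within 4 s after task onset, frequency
    band within 1-40 Hz (covering the mu/alpha 8-12 Hz and beta 14-30 Hz
    sensorimotor rhythms).  Minimum widths keep every candidate segment a
    realizable band-pass filter and non-empty time crop.
    """

    fmin: float = 1.0
    fmax: float = 40.0
    tmin: float = 0.0
    tmax: float = 4.0
    min_fwidth: float = 2.0
    min_twidth: float = 0.5

    def __post_init__(self) -> None:
        if self.fmax - self.fmin < self.min_fwidth or self.min_fwidth <= 0:
            raise ValueError("frequency range narrower than the minimum band width")
        if self.tmax - self.tmin < self.min_twidth or self.min_twidth <= 0:
            raise ValueError("time range shorter than the minimum window width")


def decode_position(position, bounds: SearchBounds) -> TimeFreqSegment:
    """Map a normalized 4-vector onto a valid segment (total function).

    Components are clipped to [0, 1] and mapped affinely, width after start:

    - ``fstart = fmin + p0 * (fmax - min_fwidth - fmin)``
    - ``fwidth = min_fwidth + p1 * (fmax - fstart - min_fwidth)``

    and analogously in time.  Every point of [0,1]^4 yields a segment
    satisfying the bounds, and every valid segment is reachable, so the
    optimizer needs no rejection or repair step.
    """
    p = np.clip(np.asarray(position, dtype=float), 0.0, 1.0)
    if p.shape != (4,):
        raise ValueError(f"position must be a 4-vector, got shape {p.shape}")
    if not np.all(np.isfinite(np.asarray(position, dtype=float))):
        raise ValueError("position components must be finite")
    b = bounds
    fstart = b.fmin + p[0] * (b.fmax - b.min_fwidth - b.fmin)
    fwidth = b.min_fwidth + p[1] * (b.fmax - fstart - b.min_fwidth)
    tstart = b.tmin + p[2] * (b.tmax - b.min_twidth - b.tmin)
    twidth = b.min_twidth + p[3] * (b.tmax - tstart - b.min_twidth)
    return TimeFreqSegment(fstart=fstart, fwidth=fwidth, tstart=tstart, twidth=twidth)


def apply_segment(epochs, seg: TimeFreqSegment):
    """Crop epochs to the segment's time window, then band-pass to its band.

    Crop-then-filter order is fixed: with zero-phase filtering the
    difference versus filter-then-crop is confined to the window edges.
    Raises ``ValueError`` if the band's upper edge reaches the Nyquist
    frequency of the data.
    """
    from . import preprocess

    nyq = epochs.sfreq / 2.0
    if seg.fstop >= nyq:
        raise ValueError(
            f"segment band edge {seg.fstop:g} Hz >= Nyquist {nyq:g} Hz; "
            "resample or shrink the frequency bounds"
        )
    cropped = preprocess.crop_time(epochs, seg.tstart, seg.tstop)
    return preprocess.bandpass(cropped, seg.fstart, seg.fstop)


def interval_jaccard(a_start: float, a_stop: float, b_start: float, b_stop: float) -> float:
    """Jaccard overlap |A∩B| / |A∪B| of two 1-D intervals."""
    inter = max(0.0, min(a_stop, b_stop) - max(a_start, b_start))
    union = max(a_stop, b_stop) - min(a_start, b_start)
    if union <= 0:
        return 0.0
    return inter / union
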