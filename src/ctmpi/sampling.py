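"""Acquisition timing models: shuttle, non-shuttle and continuous modes.

The three dynamic scan modes differ only in *when* they read out the
contrast curves:

* ``shuttle`` — ECG-triggered at end-systole, with the table alternating
  between two positions; scans fire every other beat and alternate
  positions, so the analyzed slab is revisited every 4th beat (one image
  every 2–3 s at 107–115 bpm).
* ``non_shuttle`` — ECG-triggered at a fixed table position, one
  acquisition every beat (every 0.5–1 s).
* ``continuous`` — not ECG-synchronized; a regular 16 frames/s grid.

Sampling a dense ground-truth curve at those times (optionally averaged
over the gantry rotation window) yields the curve each mode would record.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .curves import ContrastCurve
from .errors import InvalidInputError

__all__ = [
    "ScanMode",
    "SamplingScheme",
    "SampledCurve",
    "beat_schedule",
    "acquisition_times",
    "sample_curve",
    "default_schemes",
]


class ScanMode(str, Enum):
    SHUTTLE = "shuttle"
    NON_SHUTTLE = "non_shuttle"
    CONTINUOUS = "continuous"

    @property
    def ecg_triggered(self) -> bool:
        return self is not ScanMode.CONTINUOUS


@dataclass(frozen=True)
class SamplingScheme:
    """Timing model of one acquisition mode.

    heart_rate_range
        (min, max) beats per minute; RR intervals are drawn uniformly from
        the corresponding interval of periods.
    trigger_phase
        Fraction of the RR interval at which ECG-triggered frames are taken
        (end-systole).
    slab_revisit_beats
        Beats between successive acquisitions of the analyzed slab
        (shuttle: 4, non-shuttle: 1).
    frame_interval
        Seconds between frames in continuous mode (1/16 s).
    rotation_time
        Gantry rotation time in seconds, available as an averaging window.
    duration
        Total scan time in seconds.
    """

    mode: ScanMode
    heart_rate_range: tuple[float, float] = (107.0, 115.0)
    trigger_phase: float = 0.35
    slab_revisit_beats: int = 1
    frame_interval: float = 1.0 / 16.0
    rotation_time: float = 0.25
    duration: float = 60.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ScanMode(self.mode))
        lo, hi = self.heart_rate_range
        if not (0 < lo <= hi < 300):
            raise InvalidInputError("heart_rate_range must satisfy 0 < lo <= hi < 300 bpm")
        if not 0 <= self.trigger_phase < 1:
            raise InvalidInputError("trigger_phase must be in [0, 1)")
        if self.frame_interval <= 0:
            raise InvalidInputError("frame_interval must be positive")
        if self.slab_revisit_beats < 1:
            raise InvalidInputError("slab_revisit_beats must be >= 1")
        if self.duration <= 0:
            raise InvalidInputError("duration must be positive")

    @property
    def rr_bounds(self) -> tuple[float, float]:
        """(shortest, longest) RR interval in seconds."""
        lo, hi = self.heart_rate_range
        return 60.0 / hi, 60.0 / lo


def default_schemes() -> dict[ScanMode, SamplingScheme]:
    """The three study schemes at their default settings."""
    return {
        ScanMode.SHUTTLE: SamplingScheme(ScanMode.SHUTTLE, slab_revisit_beats=4),
        ScanMode.NON_SHUTTLE: SamplingScheme(ScanMode.NON_SHUTTLE, slab_revisit_beats=1),
        ScanMode.CONTINUOUS: SamplingScheme(ScanMode.CONTINUOUS),
    }


@dataclass
class SampledCurve(ContrastCurve):
    """A contrast curve recorded at a scheme's acquisition times."""

    scheme: SamplingScheme | None = None


def beat_schedule(scheme: SamplingScheme, seed) -> np.ndarray:
    """Simulate R-wave times over the scan duration.

    Successive RR intervals are drawn independently and uniformly from
    [60/hr_max, 60/hr_min]; the first beat falls at a random offset within
    one (randomly drawn) RR interval of the scan start.  Reproducible for a
    given seed (int or Generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rr_lo, rr_hi = scheme.rr_bounds
    first_rr = rng.uniform(rr_lo, rr_hi)
    t = rng.uniform(0.0, first_rr)
    n_max = int(np.ceil(scheme.duration / rr_lo)) + 2
    intervals = rng.uniform(rr_lo, rr_hi, size=n_max)
    beats = t + np.concatenate([[0.0], np.cumsum(intervals)])
    return beats[beats <= scheme.duration]


def acquisition_times(scheme: SamplingScheme, beats=None) -> np.ndarray:
    """Acquisition times (s) of the analyzed slab for one realized scan.

    ECG-triggered modes fire at ``beat_k + trigger_phase * RR_k`` for every
    ``slab_revisit_beats``-th beat; the final beat (whose RR interval is
    unobserved) never triggers.  Continuous mode ignores the beats and
    returns the regular grid ``0, h, 2h, ...`` up to (excluding) duration.
    """
    if scheme.mode is ScanMode.CONTINUOUS:
        n = int(np.floor(scheme.duration / scheme.frame_interval))
        # endpoint-exclusive regular grid: exactly floor(D/h) frames
        times = np.arange(n) * scheme.frame_interval
        return times[times < scheme.duration]
    beats = np.asarray(beats, dtype=float) if beats is not None else np.empty(0)
    if beats.size < 2:
        raise InvalidInputError(
            "ECG-triggered modes need at least two R-wave times"
        )
    rr = np.diff(beats)
    trigger = beats[:-1] + scheme.trigger_phase * rr
    trigger = trigger[:: scheme.slab_revisit_beats]
    return trigger[trigger <= scheme.duration]


def sample_curve(
    curve: ContrastCurve,
    times,
    rotation_window: float | None = None,
    scheme: SamplingScheme | None = None,
) -> SampledCurve:
    """Read the dense curve out at discrete acquisition times.

    Point readout linearly interpolates the dense curve; with a rotation
    window ``w`` each sample is instead the mean of the curve over
    ``[t - w/2, t + w/2]`` (approximated on 17 sub-samples, exact for
    locally linear curves).  No extrapolation: all (window-extended) times
    must lie within the curve's span.
    """
    times = np.sort(np.asarray(times, dtype=float))
    if times.size < 2:
        raise InvalidInputError("need at least two acquisition times")
    lo, hi = curve.span
    half = 0.0 if rotation_window is None else rotation_window / 2.0
    if times[0] - half < lo or times[-1] + half > hi:
        raise InvalidInputError(
            f"acquisition times (±window) fall outside curve span [{lo}, {hi}]"
        )
    if rotation_window is None:
        values = np.interp(times, curve.times, curve.values)
    else:
        offsets = np.linspace(-half, half, 17)
        grid = times[:, None] + offsets[None, :]
        values = np.interp(grid, curve.times, curve.values).mean(axis=1)
    return SampledCurve(
        times=times,
        values=values,
        injection_start=curve.injection_start,
        scheme=scheme,
    )
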