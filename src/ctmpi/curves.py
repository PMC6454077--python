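"""Time–attenuation curves: the common currency of every pipeline stage.

A :class:`ContrastCurve` is a series of CT attenuation values (Hounsfield
units) over time, together with the time at which contrast injection
started.  Dense ground-truth curves, discretely sampled acquisition curves
and ROI-extracted curves are all represented this way.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidInputError

__all__ = ["ContrastCurve"]


@dataclass
class ContrastCurve:
    """A time–attenuation series.

    Parameters
    ----------
    times
        Sample times in seconds, non-negative and strictly increasing.
    values
        Attenuation in HU at each sample time; must be finite.
    injection_start
        Time of contrast injection onset relative to acquisition start, in
        seconds.  Samples before this time define the pre-injection
        baseline.
    """

    times: np.ndarray
    values: np.ndarray
    injection_start: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise InvalidInputError("times and values must be 1-D arrays")
        if self.times.size != self.values.size:
            raise InvalidInputError(
                f"times ({self.times.size}) and values ({self.values.size}) "
                "must have equal length"
            )
        if self.times.size < 2:
            raise InvalidInputError("a curve needs at least 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.times[0] < 0:
            raise InvalidInputError("times must be non-negative")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("all curve values must be finite")
        self.injection_start = float(self.injection_start)
        if not 0 <= self.injection_start < self.times[-1]:
            raise InvalidInputError(
                "injection_start must lie in [0, final sample time)"
            )

    # -- basic queries -----------------------------------------------------

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) sample time in seconds."""
        return float(self.times[0]), float(self.times[-1])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def at(self, t) -> np.ndarray:
        """Linear interpolation of the curve at time(s) ``t`` (no extrapolation)."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.span
        if np.any(t < lo) or np.any(t > hi):
            raise InvalidInputError(
                f"requested time outside curve span [{lo}, {hi}]"
            )
        return np.interp(t, self.times, self.values)

    def pre_injection_baseline(self) -> float:
        """Mean value of samples strictly before ``injection_start``.

        Falls back to the first sample when no sample precedes injection
        (e.g. a curve cropped to the uptake phase).
        """
        mask = self.times < self.injection_start
        if mask.any():
            return float(self.values[mask].mean())
        return float(self.values[0])

    def enhancement(self, baseline: float | None = None) -> np.ndarray:
        """Baseline-subtracted values; default baseline is pre-injection mean."""
        if baseline is None:
            baseline = self.pre_injection_baseline()
        return self.values - baseline

    def replace(self, **changes) -> "ContrastCurve":
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_csv(self, path: str | Path, **metadata) -> None:
        """Write ``time_s,value_hu`` CSV plus a JSON metadata sidecar.

        The sidecar (same stem, ``.json`` suffix) records injection_start,
        units and any extra key/value metadata supplied.
        """
        path = Path(path)
        header = "time_s,value_hu"
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            delimiter=",",
            header=header,
            comments="",
            fmt="%.10g",
        )
        sidecar = {
            "injection_start_s": self.injection_start,
            "units": {"time": "s", "value": "HU"},
            **metadata,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ContrastCurve":
        """Read a curve written by :meth:`to_csv` (sidecar optional)."""
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        injection_start = 0.0
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            injection_start = float(meta.get("injection_start_s", 0.0))
        return cls(times=data[:, 0], values=data[:, 1], injection_start=injection_start)
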