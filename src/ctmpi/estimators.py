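"""MBF quantification: maximum upslope, true flow, Patlak K1 and F = K1/E.

The maximum-upslope model estimates perfusion as the maximum rate of rise
of the tissue attenuation curve divided by the peak arterial enhancement,

    MBF = 60 * max d(TAC)/dt / (peak(AIF) * rho)        [mL/g/min]

which is unbiased only when (i) the sampling actually captures the TAC's
steepest rise and the AIF's peak, and (ii) the extraction fraction is 1.
The Patlak graphical method instead regresses C_t(T)/c_a(T) on
∫c_a dt / c_a(T) over an early window; its slope estimates the transfer
constant K1 = E*F, and dividing by a known extraction fraction converts it
back to flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .curves import ContrastCurve
from .errors import EstimationError, InvalidInputError

__all__ = [
    "Method",
    "UpslopeConfig",
    "MbfEstimate",
    "baseline_value",
    "max_upslope",
    "peak_enhancement",
    "mbf_upslope",
    "true_mbf",
    "patlak_k1",
    "default_patlak_window",
    "flow_from_k1",
]

log = logging.getLogger(__name__)


class Method(str, Enum):
    UPSLOPE = "upslope"
    PATLAK = "patlak"


@dataclass(frozen=True)
class UpslopeConfig:
    """Knobs of the slope/peak estimation.

    slope_window
        Number of consecutive samples per local least-squares line fit
        (>= 2; 2 reduces to the forward finite difference).  ECG-triggered
        modes default to 3; for the 16 Hz continuous mode a window spanning
        ~1 s (17 samples) suppresses frame noise.
    baseline_window_end
        Samples before this time (s) define the pre-injection baseline.
    smoothing
        Optional moving-average width in samples applied before the slope
        search; ``None`` disables it.
    """

    slope_window: int = 3
    baseline_window_end: float = 5.0
    smoothing: int | None = None

    def __post_init__(self) -> None:
        if self.slope_window < 2:
            raise InvalidInputError("slope_window must be >= 2")
        if self.baseline_window_end <= 0:
            raise InvalidInputError("baseline_window_end must be positive")
        if self.smoothing is not None and self.smoothing < 1:
            raise InvalidInputError("smoothing width must be >= 1 sample")


@dataclass(frozen=True)
class MbfEstimate:
    """One estimated MBF value with the components that produced it."""

    value: float                  # mL/g/min
    method: Method
    max_slope: float | None = None   # HU/s (upslope only)
    aif_peak: float | None = None    # HU enhancement (upslope only)
    k1: float | None = None          # mL/g/min (Patlak only)


def baseline_value(curve: ContrastCurve, cfg: UpslopeConfig = UpslopeConfig()) -> float:
    """Mean of all samples before ``baseline_window_end`` (pre-injection HU)."""
    mask = curve.times < cfg.baseline_window_end
    if not mask.any():
        raise EstimationError(
            f"no samples before baseline_window_end={cfg.baseline_window_end} s; "
            "cannot establish a pre-injection baseline"
        )
    return float(curve.values[mask].mean())


def _smooth(times: np.ndarray, values: np.ndarray, width: int):
    if width is None or width <= 1:
        return times, values
    kernel = np.full(width, 1.0 / width)
    values = np.convolve(values, kernel, mode="valid")
    # centre of each averaging window
    tker = np.full(width, 1.0 / width)
    times = np.convolve(times, tker, mode="valid")
    return times, values


def _sliding_ls_slopes(times: np.ndarray, values: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope of value vs time over every run of `window` samples."""
    t = times - times.mean()   # guard against cancellation at large t
    v = values
    ones = np.ones(window)
    s_t = np.convolve(t, ones, "valid")
    s_v = np.convolve(v, ones, "valid")
    s_tt = np.convolve(t * t, ones, "valid")
    s_tv = np.convolve(t * v, ones, "valid")
    denom = window * s_tt - s_t**2
    return (window * s_tv - s_t * s_v) / denom


def max_upslope(curve: ContrastCurve, cfg: UpslopeConfig = UpslopeConfig()) -> float:
    """Maximum local least-squares slope of the curve, in HU/s.

    With ``slope_window = 2`` this is the maximum forward finite-difference
    slope.  A constant curve yields 0; the result may be negative for a
    strictly decreasing curve (callers floor at zero when converting to
    flow).
    """
    times, values = _smooth(curve.times, curve.values, cfg.smoothing)
    if times.size < cfg.slope_window:
        raise EstimationError(
            f"curve has {times.size} usable samples, fewer than "
            f"slope_window={cfg.slope_window}"
        )
    return float(_sliding_ls_slopes(times, values, cfg.slope_window).max())


def peak_enhancement(aif_curve: ContrastCurve, cfg: UpslopeConfig = UpslopeConfig()) -> float:
    """Peak arterial enhancement: max sample minus baseline, floored at 0 (HU)."""
    base = baseline_value(aif_curve, cfg)
    return max(float(aif_curve.values.max() - base), 0.0)


def mbf_upslope(
    tac: ContrastCurve,
    aif: ContrastCurve,
    cfg: UpslopeConfig = UpslopeConfig(),
    tissue_density: float = 1.05,
) -> MbfEstimate:
    """Maximum-upslope MBF: 60 * maxslope(TAC) / (peak(AIF) * rho), mL/g/min."""
    peak = peak_enhancement(aif, cfg)
    if peak <= 0:
        raise EstimationError("AIF peak enhancement is zero; cannot normalize upslope")
    slope = max_upslope(tac, cfg)
    value = 60.0 * slope / (peak * tissue_density)
    if value < 0:
        log.warning("negative upslope MBF %.4g floored at zero", value)
        value = 0.0
    return MbfEstimate(value=value, method=Method.UPSLOPE, max_slope=slope, aif_peak=peak)


def true_mbf(input_flow: float, heart_weight: float) -> float:
    """Reference perfusion from the pump: input flow (mL/min) / weight (g)."""
    if heart_weight <= 0:
        raise InvalidInputError("heart_weight must be positive")
    if input_flow < 0:
        raise InvalidInputError("input_flow must be non-negative")
    return input_flow / heart_weight


def default_patlak_window(
    aif: ContrastCurve,
    cfg: UpslopeConfig = UpslopeConfig(),
    arrival_fraction: float = 0.1,
) -> tuple[float, float]:
    """Early-phase fit window: contrast arrival to the AIF peak time.

    Arrival is the first sample at/after injection whose enhancement
    exceeds ``arrival_fraction`` of the peak (a threshold comfortably above
    CT noise); the window closes at the sampled AIF maximum, before
    back-flux accumulates.
    """
    base = baseline_value(aif, cfg)
    enh = aif.values - base
    i_peak = int(np.argmax(enh))
    t_peak = float(aif.times[i_peak])
    thresh = arrival_fraction * enh[i_peak]
    after = (aif.times >= aif.injection_start) & (enh > thresh)
    if not after.any():
        raise EstimationError("no arterial enhancement found after injection")
    t_arrival = float(aif.times[after.argmax()])
    if t_arrival >= t_peak:
        raise EstimationError("degenerate Patlak window: arrival at/after AIF peak")
    return t_arrival, t_peak


def patlak_k1(
    tac: ContrastCurve,
    aif: ContrastCurve,
    cfg: UpslopeConfig = UpslopeConfig(),
    fit_window: tuple[float, float] | None = None,
    tissue_density: float = 1.05,
) -> MbfEstimate:
    """Patlak transfer constant K1 from the early-window graphical fit.

    Regresses y(T) = C_t(T)/c_a(T) on x(T) = ∫0..T c_a dt / c_a(T)
    (baseline-subtracted, trapezoid integral over the available samples)
    for samples inside ``fit_window`` with positive arterial enhancement.
    K1 = 60 * slope / rho in mL/g/min.  TAC and AIF must share the same
    acquisition times.
    """
    if tac.times.size != aif.times.size or not np.allclose(tac.times, aif.times):
        raise InvalidInputError("Patlak requires TAC and AIF on the same sample times")
    if fit_window is None:
        fit_window = default_patlak_window(aif, cfg)
    t0, t1 = fit_window
    c_a = aif.values - baseline_value(aif, cfg)
    c_t = tac.values - baseline_value(tac, cfg)
    integral = cumulative_trapezoid(c_a, aif.times, initial=0.0)
    mask = (aif.times >= t0) & (aif.times <= t1) & (c_a > 0)
    if mask.sum() < 3:
        raise EstimationError(
            f"only {int(mask.sum())} usable samples in Patlak window [{t0:.3g}, {t1:.3g}] s"
        )
    x = integral[mask] / c_a[mask]
    y = c_t[mask] / c_a[mask]
    if np.ptp(x) < 1e-12 or np.var(x) == 0:
        raise EstimationError("degenerate Patlak regressor: no spread in normalized time")
    slope, _intercept = np.polyfit(x, y, 1)
    k1 = 60.0 * float(slope) / tissue_density
    if k1 < 0:
        log.warning("negative Patlak K1 %.4g floored at zero", k1)
        k1 = 0.0
    return MbfEstimate(value=k1, method=Method.PATLAK, k1=k1)


def flow_from_k1(k1: float, extraction_e: float) -> float:
    """Extraction-fraction flow correction F = K1 / E (mL/g/min)."""
    if not 0 < extraction_e <= 1:
        raise InvalidInputError("extraction_e must be in (0, 1]")
    return k1 / extraction_e
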