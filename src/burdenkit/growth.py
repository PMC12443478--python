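"""Growth kinetics: maximum specific growth rate (MGR), lag time, and
summaries of generic kinetic series.

Batch growth monitored as optical density (OD660, typically every 10 min)
is summarised by the maximum specific growth rate: the steepest sustained
slope of ln(OD) during exponential phase.  The estimator slides a
fixed-duration window along the series, fits ordinary least squares to
ln(blank-subtracted OD) inside each window, and reports the maximum slope
among windows whose mean OD clears a floor (so that pre-growth baseline
noise cannot win).  Rates are ingested in minutes and reported per hour.

Fluorescence reporter series are summarised by their maximum signal, and
oxygen-consumption kinetics by the slope of a straight-line fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientGrowthError, UndefinedRatioError, ValidationError

# Minimum samples for any windowed log-linear fit.
MIN_WINDOW_POINTS = 5
# Minimum series length for MGR estimation.
MIN_CURVE_POINTS = 8
# OD values at or below this after blank subtraction are excluded from log fits.
OD_EPSILON = 1e-9

__all__ = [
    "GrowthCurve",
    "MGRResult",
    "KineticSeries",
    "estimate_mgr",
    "relative_mgr",
    "max_signal",
    "linear_slope",
    "read_curves_csv",
]


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD time series.

    times are minutes since inoculation (strictly increasing); od is
    blank-uncorrected or corrected optical density depending on
    ``blank_subtracted``.
    """

    times: np.ndarray
    od: np.ndarray
    strain: str = ""
    condition: str = ""
    replicate: int = 0
    blank_subtracted: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.ndim != 1 or times.size != od.size:
            raise ValidationError("times and od must be 1-D arrays of equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValidationError("times must be strictly increasing")
        if self.blank_subtracted and np.any(od < 0):
            raise ValidationError("blank-subtracted od values must be >= 0")


@dataclass(frozen=True)
class MGRResult:
    """Maximum growth rate estimate for one curve.

    mgr is per hour; window is the (start_min, end_min) of the maximising
    window; lag_min is where the back-extrapolated exponential through that
    window crosses the initial OD; fit_quality is the window fit's R^2.
    """

    mgr: float
    window: tuple[float, float]
    lag_min: float
    final_od: float
    fit_quality: float
    strain: str = ""
    condition: str = ""
    replicate: int = 0


@dataclass(frozen=True)
class KineticSeries:
    """A generic timestamped signal (fluorescence, oxygen probe, ...)."""

    times: np.ndarray
    values: np.ndarray
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise ValidationError("times and values must be 1-D arrays of equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValidationError("times must be strictly increasing")


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of an ordinary least-squares line fit."""
    xm = x.mean()
    ym = y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise ValidationError("degenerate fit: zero variance in x")
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    syy = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if syy == 0.0 else 1.0 - float(np.sum(resid**2)) / syy
    return slope, intercept, r2


def estimate_mgr(
    curve: GrowthCurve,
    window_min: float = 120.0,
    od_floor: float = 0.05,
    od_blank: float = 0.0,
) -> MGRResult:
    """Estimate the maximum specific growth rate of a batch growth curve.

    Slides every contiguous window of duration ``window_min`` along the
    series, fits OLS to ln(od - od_blank) within the window, and returns
    the maximum slope (converted to per hour) among windows whose mean OD
    is at least ``od_floor``.  Negative maximum slopes are reported as 0
    (no growth).  Lag is where the maximising window's exponential,
    extrapolated back, crosses the first observed OD.

    Raises
    ------
    InsufficientGrowthError
        If fewer than ``MIN_CURVE_POINTS`` usable points lie above the
        floor, or no window qualifies.
    ValidationError
        For malformed input or a window spanning < 5 samples.
    """
    if od_floor <= 0:
        raise ValidationError("od_floor must be > 0")
    times = curve.times
    od = curve.od - od_blank

    neg = od <= 0
    if np.any(neg):
        warnings.warn(
            f"{int(neg.sum())} OD values <= blank; clipped to epsilon and "
            "excluded from log fits",
            stacklevel=2,
        )
    usable = ~neg
    log_od = np.full_like(od, np.nan)
    log_od[usable] = np.log(od[usable])

    above = usable & (od >= od_floor)
    if int(above.sum()) < MIN_CURVE_POINTS:
        raise InsufficientGrowthError(
            f"insufficient growth: only {int(above.sum())} points above "
            f"od_floor={od_floor} (need >= {MIN_CURVE_POINTS})"
        )

    n = times.size
    best: tuple[float, float, float, int, int] | None = None  # slope, icept, r2, i, j
    for i in range(n):
        # largest j with times[j] <= times[i] + window_min
        j = int(np.searchsorted(times, times[i] + window_min, side="right")) - 1
        if j <= i:
            continue
        sel = slice(i, j + 1)
        ok = usable[sel]
        if int(ok.sum()) < MIN_WINDOW_POINTS:
            continue
        if float(np.mean(od[sel][ok])) < od_floor:
            continue
        t_w = times[sel][ok]
        y_w = log_od[sel][ok]
        slope, icept, r2 = _ols_line(t_w, y_w)
        if best is None or slope > best[0]:
            best = (slope, icept, r2, i, j)

    if best is None:
        raise InsufficientGrowthError(
            "insufficient growth: no window satisfies the floor and size constraints"
        )

    slope, icept, r2, i, j = best
    mgr_per_h = max(slope, 0.0) * 60.0
    final_od = float(np.max(curve.od))

    # Lag: back-extrapolate ln(od) = icept + slope*t to the initial OD.
    od0 = od[usable][0] if np.any(usable) else OD_EPSILON
    if slope > 0:
        lag = (np.log(od0) - icept) / slope
        lag = float(max(lag, 0.0))
    else:
        lag = float(times[-1])

    return MGRResult(
        mgr=float(mgr_per_h),
        window=(float(times[i]), float(times[j])),
        lag_min=lag,
        final_od=final_od,
        fit_quality=float(r2),
        strain=curve.strain,
        condition=curve.condition,
        replicate=curve.replicate,
    )


def relative_mgr(sample: MGRResult, control: MGRResult) -> float:
    """Sample MGR as a percent of the control MGR (the %MGR quantity)."""
    if control.mgr <= 0:
        raise UndefinedRatioError("control MGR is zero; relative MGR undefined")
    return 100.0 * sample.mgr / control.mgr


def max_signal(series: KineticSeries) -> float:
    """Maximum of a kinetic signal (e.g. peak reporter fluorescence)."""
    if series.values.size == 0:
        raise ValidationError("empty series")
    return float(np.max(series.values))


def linear_slope(series: KineticSeries) -> float:
    """OLS slope of signal vs time, per minute (e.g. oxygen-consumption rate)."""
    if series.values.size < 3:
        raise ValidationError("linear_slope requires >= 3 points")
    slope, _, _ = _ols_line(series.times, series.values)
    return float(slope)


def read_curves_csv(path) -> list[GrowthCurve]:
    """Read long-format growth curves (time_min, od, strain, condition, replicate)."""
    df = pd.read_csv(path)
    required = {"time_min", "od", "strain", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"curves CSV missing columns: {sorted(missing)}")
    curves = []
    for (strain, condition, rep), grp in df.groupby(
        ["strain", "condition", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_min")
        curves.append(
            GrowthCurve(
                times=grp["time_min"].to_numpy(float),
                od=grp["od"].to_numpy(float),
                strain=str(strain),
                condition=str(condition),
                replicate=int(rep),
            )
        )
    return curves
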