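"""Patlak-plot estimation of Ktrans and v_p.

Dividing the unidirectional two-compartment model by C_p(t) gives the
Patlak linearisation

    C_t(t)/C_p(t) = v_p + Ktrans * t_stretch(t),

a straight line in the (t_stretch, v_d) plane whose slope is the influx
constant and whose intercept is the fractional plasma volume. Two
fitting modes are provided: ordinary least squares with both parameters
free (the conventional Patlak plot) and a one-parameter variant with
v_p supplied and fixed (Step 3 of the hybrid method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InsufficientDataError, InvalidParameterError
from .kinetics import (
    DEFAULT_CP_FLOOR_FRAC,
    ConcCurve,
    StretchSeries,
    stretch_time,
)

__all__ = [
    "StretchInterval",
    "PatlakFit",
    "patlak_points",
    "patlak_fit",
    "patlak_fit_fixed_vp",
    "INTERVAL_85_250",
    "INTERVAL_85_300",
    "INTERVAL_0_250",
    "INTERVAL_0_460",
]


@dataclass(frozen=True)
class StretchInterval:
    """An inclusive fitting window [lo, hi] on the t_stretch axis, seconds."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise InvalidParameterError("require 0 <= lo < hi")

    def contains(self, x: np.ndarray) -> np.ndarray:
        return (x >= self.lo) & (x <= self.hi)


#: Standard fitting-interval presets, seconds of stretched time.
INTERVAL_85_250 = StretchInterval(85.0, 250.0)
INTERVAL_85_300 = StretchInterval(85.0, 300.0)
INTERVAL_0_250 = StretchInterval(0.0, 250.0)
INTERVAL_0_460 = StretchInterval(0.0, 460.0)


@dataclass
class PatlakFit:
    """Result of a Patlak regression.

    ktrans : slope, min^-1
    vp     : intercept, dimensionless
    n_points : samples used in the regression
    r2     : coefficient of determination of the line
    """

    ktrans: float
    vp: float
    n_points: int
    r2: float

    def to_dict(self) -> dict:
        return {
            "ktrans_per_min": self.ktrans,
            "vp": self.vp,
            "n_points": self.n_points,
            "r2": self.r2,
        }


def patlak_points(
    ct: ConcCurve, cp: ConcCurve, cp_floor_frac: float = DEFAULT_CP_FLOOR_FRAC
) -> StretchSeries:
    """Patlak-plot samples (t_stretch, v_d) from a tissue/plasma curve pair.

    Both curves are baseline-subtracted; v_d = C_t/C_p is computed on the
    samples where C_p exceeds the floor fraction of its peak.
    """
    if ct.t.shape != cp.t.shape or not np.allclose(ct.t, cp.t, rtol=0, atol=1e-9):
        raise AlignmentError("tissue and plasma curves must share the time grid")
    series = stretch_time(cp, cp_floor_frac)
    cps = cp.baseline_subtracted()
    cts = ct.baseline_subtracted()
    with np.errstate(divide="ignore", invalid="ignore"):
        vd = np.where(series.valid, cts.c / np.where(series.valid, cps.c, 1.0), np.nan)
    series.vd = vd
    return series


def _select(points: StretchSeries, iv: StretchInterval) -> tuple[np.ndarray, np.ndarray]:
    m = points.valid & np.isfinite(points.vd) & np.isfinite(points.t_stretch)
    m &= iv.contains(points.t_stretch)
    return points.t_stretch[m], points.vd[m]


def patlak_fit(points: StretchSeries, iv: StretchInterval) -> PatlakFit:
    """Ordinary least-squares Patlak line over the selected interval.

    The slope (per second of stretched time) is converted to min^-1.
    Unweighted OLS; negative fitted values are reported as-is.
    """
    x, y = _select(points, iv)
    if x.size < 2:
        raise InsufficientDataError(
            f"need >= 2 valid points in t_stretch [{iv.lo}, {iv.hi}], got {x.size}"
        )
    xm = x.mean()
    ym = y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise InsufficientDataError("all selected t_stretch values identical")
    slope = float(np.sum((x - xm) * (y - ym))) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return PatlakFit(ktrans=slope * 60.0, vp=intercept, n_points=int(x.size), r2=r2)


def patlak_fit_fixed_vp(
    points: StretchSeries, vp: float, iv: StretchInterval
) -> float:
    """One-parameter Patlak slope with the intercept fixed at ``vp``.

    Least squares through the fixed intercept:
    Ktrans = sum(x (y - vp)) / sum(x^2) over the selected points,
    returned in min^-1.
    """
    if not np.isfinite(vp):
        raise InvalidParameterError("vp must be finite")
    x, y = _select(points, iv)
    if x.size < 1:
        raise InsufficientDataError(
            f"no valid points in t_stretch [{iv.lo}, {iv.hi}]"
        )
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise InsufficientDataError("selected t_stretch values are all zero")
    slope = float(np.sum(x * (y - vp))) / sxx
    return slope * 60.0
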