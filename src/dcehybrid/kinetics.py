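"""Tracer-kinetic forward models and the concentration-stretched time axis.

Two forward models are provided for the tissue concentration C_t(t) given
a plasma curve C_p(t):

* the unidirectional two-compartment (Patlak) model
      C_t = v_p C_p + Ktrans * cumint(C_p),
  which assumes no backflux from the interstitium to plasma, and
* the modified Tofts model
      C_t = v_p C_p + Ktrans * conv(C_p, exp(-k_ep t)),   k_ep = Ktrans/v_e,
  which allows bidirectional exchange with the extravascular
  extracellular space (EES).

The Patlak abscissa is "concentration-stretched time"
t_stretch(t) = cumint(C_p)(t) / C_p(t); it equals lab time for constant
C_p and stretches wherever the plasma concentration decays.

Unit convention: Ktrans and k_ep are carried in min^-1 (the standard
reporting unit) and converted to s^-1 only at the integration boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import (
    EmptySeriesError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "ConcCurve",
    "DynSeries",
    "KineticParams",
    "StretchSeries",
    "cum_integral",
    "tissue_conc_unidirectional",
    "tissue_conc_tofts",
    "stretch_time",
    "MIN_PER_S",
]

#: Conversion factor: value[min^-1] * MIN_PER_S = value[s^-1].
MIN_PER_S = 1.0 / 60.0

#: Fraction of the peak plasma concentration below which t_stretch samples
#: are masked invalid (division by a vanishing C_p).
DEFAULT_CP_FLOOR_FRAC = 0.05


def _validate_time_axis(t: np.ndarray) -> float:
    if t.ndim != 1 or t.size < 2:
        raise InvalidInputError("time axis must be 1-D with at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InvalidInputError("time axis must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InvalidInputError("time axis must be uniformly sampled")
    return float(dt[0])


@dataclass
class ConcCurve:
    """A uniformly sampled contrast-agent concentration time series.

    Attributes
    ----------
    t : lab time in seconds, strictly increasing, uniform spacing
    c : concentration in mM (may be negative: noise and inversion
        artefacts are propagated, not clipped)
    n_baseline : number of pre-injection frames at the start of the series
    """

    t: np.ndarray
    c: np.ndarray
    n_baseline: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.t.shape != self.c.shape:
            raise InvalidInputError("t and c must have equal length")
        self.dt = _validate_time_axis(self.t)
        if not 0 <= self.n_baseline <= self.t.size:
            raise InvalidInputError("n_baseline out of range")

    def baseline_mean(self) -> float:
        """Mean concentration over the baseline frames (0.0 if none)."""
        if self.n_baseline == 0:
            return 0.0
        return float(np.mean(self.c[: self.n_baseline]))

    def baseline_subtracted(self) -> "ConcCurve":
        """Copy with the baseline mean removed from every frame."""
        return ConcCurve(self.t.copy(), self.c - self.baseline_mean(), self.n_baseline)


@dataclass
class DynSeries:
    """A uniformly sampled signal-intensity time series (voxel or ROI)."""

    t: np.ndarray
    si: np.ndarray
    n_baseline: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.si = np.asarray(self.si, dtype=float)
        if self.t.shape != self.si.shape:
            raise InvalidInputError("t and si must have equal length")
        self.dt = _validate_time_axis(self.t)
        if not 0 <= self.n_baseline <= self.t.size:
            raise InvalidInputError("n_baseline out of range")


@dataclass
class KineticParams:
    """Kinetic parameters of the two-compartment tissue models.

    ktrans : volume transfer constant, min^-1
    vp     : fractional plasma volume (dimensionless, in [0, 1])
    ve     : fractional EES volume (dimensionless, in (0, 1]); optional,
             only required by the modified Tofts model
    kep    : backflux rate constant ktrans/ve, min^-1 (derived)
    """

    ktrans: float
    vp: float
    ve: float | None = None
    kep: float = field(init=False, default=np.nan)

    def __post_init__(self) -> None:
        if not 0 <= self.vp <= 1:
            raise InvalidParameterError("vp must lie in [0, 1]")
        if self.ve is not None:
            if not 0 < self.ve <= 1e12:
                raise InvalidParameterError("ve must be positive")
            self.kep = self.ktrans / self.ve


@dataclass
class StretchSeries:
    """Patlak-plot samples: stretched time, volume of distribution, validity.

    t_stretch : concentration-stretched time, s
    vd        : apparent volume of distribution C_t/C_p (NaN where unset)
    valid     : mask of usable samples (C_p above the floor)
    """

    t_stretch: np.ndarray
    vd: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t_stretch = np.asarray(self.t_stretch, dtype=float)
        self.vd = np.asarray(self.vd, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not self.t_stretch.shape == self.vd.shape == self.valid.shape:
            raise InvalidInputError("t_stretch, vd and valid must have equal length")


def cum_integral(curve: ConcCurve) -> ConcCurve:
    """Cumulative trapezoidal integral of a curve; starts at 0, units mM*s."""
    integ = cumulative_trapezoid(curve.c, curve.t, initial=0.0)
    return ConcCurve(curve.t.copy(), integ, curve.n_baseline)


def tissue_conc_unidirectional(
    cp: ConcCurve, p: KineticParams, allow_negative: bool = False
) -> ConcCurve:
    """Unidirectional two-compartment model: C_t = vp C_p + Ktrans cumint(C_p)."""
    if not allow_negative and (p.ktrans < 0 or p.vp < 0):
        raise InvalidParameterError(
            "negative ktrans/vp rejected for forward synthesis (set allow_negative)"
        )
    ktrans_s = p.ktrans * MIN_PER_S
    integ = cum_integral(cp).c
    return ConcCurve(cp.t.copy(), p.vp * cp.c + ktrans_s * integ, cp.n_baseline)


def _exp_conv_piecewise_linear(c: np.ndarray, dt: float, kep_s: float) -> np.ndarray:
    """conv(c, exp(-kep_s t)) for piecewise-linear c, exact per segment.

    Recursive update: I_{n+1} = I_n e^-a + dt [c_n f1(a) + c_{n+1} f2(a)],
    a = kep_s dt, f1 = (1 - e^-a - a e^-a)/a^2, f2 = (a - 1 + e^-a)/a^2.
    Series expansions guard the a -> 0 limit (f1 = f2 = 1/2: trapezoid).
    """
    a = kep_s * dt
    if a < 1e-6:
        # second-order accurate small-a limit
        f1 = 0.5 - a / 3.0
        f2 = 0.5 - a / 6.0
        decay = 1.0 - a + a * a / 2.0
    else:
        e = np.exp(-a)
        f1 = (1.0 - e - a * e) / (a * a)
        f2 = (a - 1.0 + e) / (a * a)
        decay = e
    out = np.empty_like(c)
    out[0] = 0.0
    acc = 0.0
    w1 = dt * f1
    w2 = dt * f2
    for n in range(c.size - 1):
        acc = acc * decay + w1 * c[n] + w2 * c[n + 1]
        out[n + 1] = acc
    return out


def tissue_conc_tofts(cp: ConcCurve, p: KineticParams) -> ConcCurve:
    """Modified Tofts model with plasma term and backflux.

    C_t = vp C_p + Ktrans * int_0^t C_p(tau) exp(-kep (t - tau)) dtau,
    evaluated with an exact recursive exponential update for piecewise-
    linear C_p (no FFT; exact at coarse sampling for small kep).
    Reduces to :func:`tissue_conc_unidirectional` as ve -> infinity.
    """
    if p.ve is None or p.ve <= 0:
        raise InvalidParameterError("modified Tofts model requires ve > 0")
    if p.ktrans < 0 or p.vp < 0:
        raise InvalidParameterError("negative ktrans/vp rejected for forward synthesis")
    ktrans_s = p.ktrans * MIN_PER_S
    kep_s = p.kep * MIN_PER_S
    conv = _exp_conv_piecewise_linear(cp.c, cp.dt, kep_s)
    return ConcCurve(cp.t.copy(), p.vp * cp.c + ktrans_s * conv, cp.n_baseline)


def stretch_time(
    cp: ConcCurve, cp_floor_frac: float = DEFAULT_CP_FLOOR_FRAC
) -> StretchSeries:
    """Concentration-stretched time  t_stretch = cumint(C_p) / C_p.

    The plasma curve is baseline-subtracted first. Samples where C_p is
    below ``cp_floor_frac`` of its peak are masked invalid (the ratio
    blows up as C_p -> 0 at baseline). vd is left NaN; pair with a tissue
    curve via :func:`dcehybrid.patlak.patlak_points` to fill it.
    """
    cps = cp.baseline_subtracted()
    peak = float(np.max(cps.c))
    if peak <= 0:
        raise EmptySeriesError("plasma curve has no positive excursion")
    floor = cp_floor_frac * peak
    integ = cum_integral(cps).c
    valid = cps.c >= floor
    if not np.any(valid):
        raise EmptySeriesError("all samples below the C_p floor")
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(valid, integ / np.where(valid, cps.c, 1.0), np.nan)
    return StretchSeries(t_stretch=ts, vd=np.full_like(ts, np.nan), valid=valid)
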