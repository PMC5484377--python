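"""First-pass (FP) estimation of the fractional plasma volume.

During the first transit of the contrast bolus the intravascular signal
dominates and backflux is negligible, so integrating concentration over
the first-pass window gives a robust plasma-volume estimate:

    v_p = int_w C_t dt / int_w C_p dt            (uncorrected)
    v_p = int_w [C_t - Ktrans cumint(C_p)] dt / int_w C_p dt
                                                 (leakage-corrected)

The leakage-corrected form subtracts the interstitial component implied
by a known Ktrans before integrating, decomposing the tissue curve into
intravascular and interstitial parts. Because the intravascular
concentration during the first pass is large compared with the leaked
amount, the corrected v_p is very insensitive to errors in the supplied
Ktrans — the property the hybrid method exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AlignmentError,
    InvalidInputError,
    InvalidParameterError,
    NoBolusError,
)
from .kinetics import MIN_PER_S, ConcCurve, cum_integral
from .patlak import INTERVAL_85_250, StretchInterval, patlak_points, patlak_fit_fixed_vp

__all__ = [
    "FirstPassWindow",
    "detect_first_pass_window",
    "vp_from_first_pass",
    "vp_leakage_corrected",
    "fp_simul",
]


@dataclass(frozen=True)
class FirstPassWindow:
    """Lab-time window [t_arrival, t_end] covering the first bolus transit."""

    t_arrival: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_arrival < self.t_end:
            raise InvalidParameterError("t_arrival must precede t_end")

    def to_dict(self) -> dict:
        return {"t_arrival_s": self.t_arrival, "t_end_s": self.t_end}


def detect_first_pass_window(
    cp: ConcCurve, k_sd: float = 5.0, min_frac_of_peak: float = 0.4
) -> FirstPassWindow:
    """Locate the first-pass transit of the bolus on a plasma curve.

    Arrival is the first frame whose (baseline-subtracted) concentration
    exceeds ``k_sd`` baseline standard deviations (with a small absolute
    guard for noiseless synthetic curves). The window ends at the first
    local minimum after the global peak — the valley between first pass
    and recirculation. If the curve decays monotonically (no
    recirculation bump) the end falls back to the first frame below
    ``min_frac_of_peak`` of the peak.
    """
    cps = cp.baseline_subtracted()
    c = cps.c
    peak_val = float(np.max(c))
    if peak_val <= 0:
        raise NoBolusError("plasma curve has no positive excursion")
    base_sd = float(np.std(c[: cp.n_baseline])) if cp.n_baseline >= 2 else 0.0
    thresh = max(k_sd * base_sd, 1e-9 * peak_val)
    above = np.nonzero(c > thresh)[0]
    if above.size == 0:
        raise NoBolusError("no sample exceeds the arrival threshold")
    i_arr = int(above[0])
    i_peak = int(np.argmax(c))
    if i_peak < i_arr:
        raise NoBolusError("global peak precedes detected arrival")
    # first strict local minimum after the peak
    i_end = None
    for i in range(i_peak + 1, c.size - 1):
        if c[i] <= c[i - 1] and c[i] < c[i + 1]:
            i_end = i
            break
    if i_end is None:
        below = np.nonzero(c[i_peak:] < min_frac_of_peak * peak_val)[0]
        if below.size == 0:
            raise NoBolusError("no post-peak valley and no decay below the floor")
        i_end = i_peak + int(below[0])
    return FirstPassWindow(t_arrival=float(cp.t[i_arr]), t_end=float(cp.t[i_end]))


def _window_slice(t: np.ndarray, w: FirstPassWindow) -> slice:
    i0 = int(np.searchsorted(t, w.t_arrival, side="left"))
    i1 = int(np.searchsorted(t, w.t_end, side="right"))
    if i1 - i0 < 2:
        raise InvalidInputError("first-pass window covers fewer than 2 samples")
    return slice(i0, i1)


def _integral_ratio(num: np.ndarray, den: np.ndarray, t: np.ndarray, w: FirstPassWindow) -> float:
    s = _window_slice(t, w)
    den_int = float(np.trapezoid(den[s], t[s]))
    if den_int <= 0:
        raise InvalidParameterError("plasma integral over the window is non-positive")
    return float(np.trapezoid(num[s], t[s])) / den_int


def vp_from_first_pass(ct: ConcCurve, cp: ConcCurve, w: FirstPassWindow) -> float:
    """Uncorrected plasma volume: ratio of first-pass areas of C_t and C_p.

    Overestimates the true v_p when leakage is present (the leaked tracer
    adds positive area to the numerator); used for the colour-coding maps.
    """
    if ct.t.shape != cp.t.shape or not np.allclose(ct.t, cp.t, rtol=0, atol=1e-9):
        raise AlignmentError("tissue and plasma curves must share the time grid")
    cts, cps = ct.baseline_subtracted(), cp.baseline_subtracted()
    return _integral_ratio(cts.c, cps.c, cp.t, w)


def vp_leakage_corrected(
    ct: ConcCurve, cp: ConcCurve, w: FirstPassWindow, ktrans: float
) -> float:
    """Leakage-corrected plasma volume with a known Ktrans (min^-1).

    The interstitial component Ktrans * cumint(C_p) is subtracted from
    the tissue curve; the remaining intravascular component is integrated
    over the first-pass window and normalised by the plasma area. With
    ktrans = 0 this reduces to :func:`vp_from_first_pass`; on noiseless
    unidirectional data with the true Ktrans it is exact.
    """
    if not np.isfinite(ktrans):
        raise InvalidParameterError("ktrans must be finite")
    if ct.t.shape != cp.t.shape or not np.allclose(ct.t, cp.t, rtol=0, atol=1e-9):
        raise AlignmentError("tissue and plasma curves must share the time grid")
    cts, cps = ct.baseline_subtracted(), cp.baseline_subtracted()
    civ = cts.c - (ktrans * MIN_PER_S) * cum_integral(cps).c
    return _integral_ratio(civ, cps.c, cp.t, w)


def fp_simul(
    ct: ConcCurve,
    cp: ConcCurve,
    w: FirstPassWindow | None = None,
    iv: StretchInterval = INTERVAL_85_250,
    n_iter: int = 10,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Experimental simultaneous FP estimator of (vp, ktrans) by alternation.

    Iterates: v_p from the leakage-corrected first-pass ratio with the
    current Ktrans, then Ktrans from a fixed-vp Patlak fit with the new
    v_p, until both stabilise. Not on the hybrid path; provided for
    comparison with the stepwise scheme.
    """
    if w is None:
        w = detect_first_pass_window(cp)
    points = patlak_points(ct, cp)
    ktrans = 0.0
    vp = vp_from_first_pass(ct, cp, w)
    for _ in range(n_iter):
        vp_new = vp_leakage_corrected(ct, cp, w, ktrans)
        ktrans_new = patlak_fit_fixed_vp(points, vp_new, iv)
        if abs(vp_new - vp) < tol and abs(ktrans_new - ktrans) < tol:
            vp, ktrans = vp_new, ktrans_new
            break
        vp, ktrans = vp_new, ktrans_new
    return vp, ktrans
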