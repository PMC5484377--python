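"""ΔR1 mapping, four-colour white-matter classification, ROI statistics.

After contrast injection the longitudinal relaxation rate of tissue
increases in proportion to the residual gadolinium concentration;
ΔR1 = R1_post - R1_N is therefore a direct, model-free index of
contrast accumulation. White matter is partitioned into four regions by
the magnitude of ΔR1 (s^-1) together with the uncorrected first-pass
plasma-volume estimate:

    blue   ΔR1 <= 0  or  vp <= 0.01
    green  0 < ΔR1 < 0.012  and  vp > 0.01
    red    0.012 <= ΔR1 < 0.025  and  vp > 0.01
    yellow ΔR1 >= 0.025  and  vp > 0.01

ROI-averaged signal curves from these regions feed the kinetic
estimators; the coefficient of variation across fitting intervals and
the ΔR1-Ktrans regression quantify estimator stability and the mapping's
validity. ANOVA/Tukey comparisons of regional means are exposed as a
thin reporting utility over scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import (
    EmptyRegionError,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)
from .kinetics import DynSeries
from .signal_model import r1_from_signal, spgr_signal

__all__ = [
    "ColorLabel",
    "RegionStats",
    "DR1_GREEN_RED",
    "DR1_RED_YELLOW",
    "VP_BLUE",
    "delta_r1_map",
    "wm_mask",
    "classify_wm",
    "classify_wm_map",
    "roi_average_curve",
    "cov",
    "regress_dr1_ktrans",
    "region_stats",
    "anova_tukey",
]

#: ΔR1 colour-band thresholds, s^-1.
DR1_GREEN_RED = 0.012
DR1_RED_YELLOW = 0.025
#: Plasma-volume threshold below which a voxel is always blue.
VP_BLUE = 0.01

#: uint8 sentinel for voxels that could not be classified (NaN inputs).
UNCLASSIFIED = 255


class ColorLabel(Enum):
    """Four-colour white-matter region label (uint8 map codes 0-3)."""

    blue = 0
    green = 1
    red = 2
    yellow = 3


@dataclass
class RegionStats:
    """Per-region summary used for the regional comparison tables."""

    region: ColorLabel
    mean_dr1: float
    mean_ktrans: float
    mean_vp: float
    n_voxels: int


def delta_r1_map(
    dyn4d: np.ndarray,
    r1n_map: np.ndarray,
    m0_map: np.ndarray,
    n_baseline: int,
    flip_deg: float = 20.0,
    tr: float = 0.005,
    n_post: int = 10,
) -> tuple[np.ndarray, int]:
    """Voxelwise ΔR1 from a 4-D dynamic series (x, y, z, t).

    SI_pre is the mean of the baseline frames and SI_post the mean of the
    last ``n_post`` frames (frame averaging suppresses Rician noise).
    R1_post is recovered with the subtraction method: the measured signal
    enhancement is added to the model-predicted native signal and the
    SPGR equation inverted in closed form. Voxels whose target signal
    leaves the attainable range become NaN.

    Returns
    -------
    (dr1_map, n_failed) : ΔR1 in s^-1 and the count of NaN voxels.
    """
    if dyn4d.ndim != 4:
        raise InvalidInputError("dynamic series must be 4-D (x, y, z, t)")
    n_t = dyn4d.shape[-1]
    if not 1 <= n_baseline < n_t or n_post < 1 or n_post > n_t - n_baseline:
        raise InvalidInputError("need >= n_post post-injection frames after baseline")
    si_pre = dyn4d[..., :n_baseline].mean(axis=-1)
    si_post = dyn4d[..., n_t - n_post :].mean(axis=-1)
    target = spgr_signal(m0_map, r1n_map, flip_deg, tr) + (si_post - si_pre)
    r1_post = r1_from_signal(target, m0_map, flip_deg, tr)
    dr1 = r1_post - r1n_map
    n_failed = int(np.count_nonzero(np.isnan(dr1)))
    return dr1, n_failed


def wm_mask(prob_map: np.ndarray, threshold: float = 0.95) -> np.ndarray:
    """Boolean white-matter mask: probability strictly greater than threshold."""
    prob_map = np.asarray(prob_map, dtype=float)
    if np.any(prob_map < 0) or np.any(prob_map > 1):
        raise InvalidInputError("probability map values must lie in [0, 1]")
    return prob_map > threshold


def classify_wm(dr1, vp_uncorrected):
    """Four-colour label for ΔR1 (s^-1) and uncorrected v_p values.

    Scalar inputs return a :class:`ColorLabel`; array inputs return a
    uint8 code map (blue 0, green 1, red 2, yellow 3) with NaN voxels set
    to the sentinel 255. ΔR1 exactly 0 and v_p exactly 0.01 fall to blue
    so the partition is exhaustive.
    """
    dr1 = np.asarray(dr1, dtype=float)
    vp = np.asarray(vp_uncorrected, dtype=float)
    scalar = dr1.ndim == 0 and vp.ndim == 0
    dr1, vp = np.atleast_1d(dr1), np.atleast_1d(vp)
    out = np.full(np.broadcast(dr1, vp).shape, UNCLASSIFIED, dtype=np.uint8)
    finite = np.isfinite(dr1) & np.isfinite(vp)
    blue = finite & ((dr1 <= 0) | (vp <= VP_BLUE))
    rest = finite & ~blue
    out[blue] = ColorLabel.blue.value
    out[rest & (dr1 < DR1_GREEN_RED)] = ColorLabel.green.value
    out[rest & (dr1 >= DR1_GREEN_RED) & (dr1 < DR1_RED_YELLOW)] = ColorLabel.red.value
    out[rest & (dr1 >= DR1_RED_YELLOW)] = ColorLabel.yellow.value
    if scalar:
        code = int(out.ravel()[0])
        return None if code == UNCLASSIFIED else ColorLabel(code)
    return out


# kept as an alias: the array form of classify_wm
classify_wm_map = classify_wm


def roi_average_curve(
    dyn4d: np.ndarray,
    labels: np.ndarray,
    region: ColorLabel,
    t: np.ndarray,
    n_baseline: int,
) -> DynSeries:
    """Frame-wise mean signal over all voxels carrying ``region``'s label."""
    if dyn4d.ndim != 4:
        raise InvalidInputError("dynamic series must be 4-D (x, y, z, t)")
    member = np.asarray(labels) == region.value
    if not np.any(member):
        raise EmptyRegionError(f"region {region.name} contains no voxels")
    return DynSeries(t=np.asarray(t, float), si=dyn4d[member].mean(axis=0), n_baseline=n_baseline)


def cov(values) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over mean.

    Returned as a fraction (0.085 = 8.5%). Undefined for fewer than two
    values or a mean indistinguishable from zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("CoV needs at least two values")
    m = v.mean()
    sd = v.std(ddof=1)
    if abs(m) < 1e-300 or (sd > 0 and abs(m) / sd < 1e-12):
        raise UndefinedStatisticError("CoV undefined: mean is ~ 0")
    return float(sd / m)


def regress_dr1_ktrans(pairs) -> tuple[float, float, float]:
    """OLS regression of Ktrans on ΔR1 over (ΔR1, Ktrans) pairs.

    Returns (slope, intercept, r2). Requires >= 2 pairs with non-constant
    ΔR1.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InsufficientDataError("need >= 2 (dr1, ktrans) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise FitFailureError("all ΔR1 values identical; regression degenerate")
    res = _stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def region_stats(
    dr1_map: np.ndarray,
    ktrans_map: np.ndarray,
    vp_map: np.ndarray,
    labels: np.ndarray,
) -> list[RegionStats]:
    """Mean ΔR1/Ktrans/v_p per colour region (NaN-aware)."""
    out = []
    for region in ColorLabel:
        m = np.asarray(labels) == region.value
        if not np.any(m):
            continue
        out.append(
            RegionStats(
                region=region,
                mean_dr1=float(np.nanmean(dr1_map[m])),
                mean_ktrans=float(np.nanmean(ktrans_map[m])),
                mean_vp=float(np.nanmean(vp_map[m])),
                n_voxels=int(np.count_nonzero(m)),
            )
        )
    return out


def anova_tukey(groups: dict) -> pd.DataFrame:
    """One-way ANOVA plus Tukey HSD over named groups of regional means.

    A thin reporting convenience over scipy.stats for user-supplied data;
    returns a tidy frame with the ANOVA row followed by one row per pair.
    """
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    if len(data) < 2:
        raise InsufficientDataError("need at least two groups")
    f, p = _stats.f_oneway(*data)
    rows = [{"comparison": "ANOVA", "statistic": float(f), "p_value": float(p)}]
    tk = _stats.tukey_hsd(*data)
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            ci = tk.confidence_interval()
            rows.append(
                {
                    "comparison": f"{names[i]} - {names[j]}",
                    "statistic": float(tk.statistic[i, j]),
                    "p_value": float(tk.pvalue[i, j]),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                }
            )
    return pd.DataFrame(rows)
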