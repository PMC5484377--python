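"""The three-step FP-Patlak hybrid estimator.

Step 1  Conventional Patlak fit over a fixed stretched-time interval
        (default 85-250 s) -> initial (Ktrans, v_p).
Step 2  Leakage-corrected first-pass v_p using the Step-1 Ktrans as a
        known value. Errors in the Step-1 Ktrans have very little effect
        here because the intravascular concentration dominates the first
        pass in low-permeability tissue.
Step 3  Patlak refit with v_p fixed at the Step-2 value, leaving Ktrans
        as the only free parameter.

The Step-2 v_p and the Step-3 Ktrans are the final outputs; the Step-1
estimates are recorded for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DceHybridError
from .first_pass import (
    FirstPassWindow,
    detect_first_pass_window,
    vp_leakage_corrected,
)
from .kinetics import DEFAULT_CP_FLOOR_FRAC, ConcCurve
from .patlak import (
    INTERVAL_85_250,
    PatlakFit,
    StretchInterval,
    patlak_fit,
    patlak_fit_fixed_vp,
    patlak_points,
)

__all__ = ["HybridResult", "hybrid_fit", "StageError"]


class StageError(DceHybridError, RuntimeError):
    """A hybrid stage failed; carries the stage name that raised."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"hybrid {stage} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class HybridResult:
    """All three stage outputs of a hybrid fit.

    ``vp_final`` (Step 2) and ``ktrans_final`` (Step 3) are the reported
    estimates; Step-1 values are diagnostic. ``step1_negative_ktrans``
    flags fits where the initial slope was negative (the correction in
    Step 2 then adds area instead of removing it).
    """

    ktrans_step1: float
    vp_step1: float
    vp_final: float
    ktrans_final: float
    interval: StretchInterval
    window: FirstPassWindow
    r2_step1: float
    n_points: int
    step1_negative_ktrans: bool

    def to_dict(self) -> dict:
        return {
            "ktrans_per_min": self.ktrans_final,
            "vp": self.vp_final,
            "step1": {
                "ktrans_per_min": self.ktrans_step1,
                "vp": self.vp_step1,
                "r2": self.r2_step1,
            },
            "n_points": self.n_points,
            "interval": [self.interval.lo, self.interval.hi],
            "window": self.window.to_dict(),
            "step1_negative_ktrans": self.step1_negative_ktrans,
        }


def hybrid_fit(
    ct: ConcCurve,
    cp: ConcCurve,
    iv: StretchInterval = INTERVAL_85_250,
    step1_interval: StretchInterval = INTERVAL_85_250,
    window: FirstPassWindow | None = None,
    cp_floor_frac: float = DEFAULT_CP_FLOOR_FRAC,
) -> HybridResult:
    """Run the three-step hybrid estimator on a tissue/plasma curve pair.

    Parameters
    ----------
    ct, cp : tissue and plasma concentration curves on a shared grid
    iv : stretched-time interval for the Step-3 refit (and the interval
        reported with the result)
    step1_interval : interval for the initial Patlak fit; kept at the
        85-250 s default even when ``iv`` is swept, matching the fixed
        Step-1 window of the method
    window : first-pass window; detected automatically when omitted

    Raises
    ------
    StageError : wrapping the underlying error, tagged with the stage.
    """
    try:
        points = patlak_points(ct, cp, cp_floor_frac)
        step1: PatlakFit = patlak_fit(points, step1_interval)
    except DceHybridError as e:
        raise StageError("step1 (Patlak)", e) from e

    try:
        if window is None:
            window = detect_first_pass_window(cp)
        vp_final = vp_leakage_corrected(ct, cp, window, step1.ktrans)
    except DceHybridError as e:
        raise StageError("step2 (first-pass vp)", e) from e

    try:
        ktrans_final = patlak_fit_fixed_vp(points, vp_final, iv)
    except DceHybridError as e:
        raise StageError("step3 (fixed-vp Patlak)", e) from e

    return HybridResult(
        ktrans_step1=step1.ktrans,
        vp_step1=step1.vp,
        vp_final=vp_final,
        ktrans_final=ktrans_final,
        interval=iv,
        window=window,
        r2_step1=step1.r2,
        n_points=step1.n_points,
        step1_negative_ktrans=bool(step1.ktrans < 0),
    )
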