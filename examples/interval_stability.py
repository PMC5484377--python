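"""Stability of the two estimators against the t_stretch interval choice.

Fits the same backflux-bearing curve over four stretched-time intervals
and reports the coefficient of variation of the resulting estimates.
The hybrid's first-pass vp does not depend on the interval at all, and
its fixed-vp slope moves far less than the free Patlak line.
"""

from dcehybrid import (
    INTERVAL_0_250,
    INTERVAL_0_460,
    INTERVAL_85_250,
    INTERVAL_85_300,
    SimConfig,
    hybrid_fit,
    patlak_fit,
    patlak_points,
    tissue_conc_tofts,
)
from dcehybrid.mapping import cov

cfg = SimConfig()
cp = cfg.plasma_curve()
ct = tissue_conc_tofts(cp, cfg.truth)
points = patlak_points(ct, cp)

rows = {"patlak": {"kt": [], "vp": []}, "hybrid": {"kt": [], "vp": []}}
for iv in (INTERVAL_85_250, INTERVAL_85_300, INTERVAL_0_250, INTERVAL_0_460):
    f = patlak_fit(points, iv)
    h = hybrid_fit(ct, cp, iv=iv)
    rows["patlak"]["kt"].append(f.ktrans)
    rows["patlak"]["vp"].append(f.vp)
    rows["hybrid"]["kt"].append(h.ktrans_final)
    rows["hybrid"]["vp"].append(h.vp_final)
    print(f"[{iv.lo:3.0f}-{iv.hi:3.0f}s]  Patlak Kt={f.ktrans:.4f} vp={f.vp:.4f}   "
          f"hybrid Kt={h.ktrans_final:.4f} vp={h.vp_final:.4f}")

print()
for m in ("patlak", "hybrid"):
    print(f"{m:7s} CoV: Ktrans {100 * cov(rows[m]['kt']):5.1f}%   vp {100 * cov(rows[m]['vp']):5.1f}%")
print("\nLower CoV across interval choices means the estimate does not hinge")
print("on an analysis decision the data cannot justify.")
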