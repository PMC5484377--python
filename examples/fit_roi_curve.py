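"""Fit one ROI-averaged uptake curve with Patlak and with the hybrid method.

Builds a noiseless white-matter-like tissue curve (modified Tofts model,
Ktrans = 0.0074 min^-1, ve = 0.20, vp = 0.024) against the default
synthetic plasma input, then fits both estimators over the standard
t_stretch interval 85-250 s. With backflux present, Patlak overestimates
vp and underestimates Ktrans; the hybrid's stepwise scheme removes most
of the vp bias and roughly halves the Ktrans bias.
"""

from dcehybrid import (
    INTERVAL_85_250,
    SimConfig,
    hybrid_fit,
    patlak_fit,
    patlak_points,
    tissue_conc_tofts,
)

cfg = SimConfig()
cp = cfg.plasma_curve()
ct = tissue_conc_tofts(cp, cfg.truth)

pat = patlak_fit(patlak_points(ct, cp), INTERVAL_85_250)
hyb = hybrid_fit(ct, cp)

print(f"truth        Ktrans = {cfg.truth.ktrans:.4f} /min   vp = {cfg.truth.vp:.4f}")
print(f"Patlak       Ktrans = {pat.ktrans:.4f} /min   vp = {pat.vp:.4f}   (r2 = {pat.r2:.5f})")
print(f"hybrid       Ktrans = {hyb.ktrans_final:.4f} /min   vp = {hyb.vp_final:.4f}")
print(f"hybrid step1 Ktrans = {hyb.ktrans_step1:.4f} /min   vp = {hyb.vp_step1:.4f}")
print()
print("Patlak's intercept absorbs leaked tracer (vp high, Ktrans low);")
print("the hybrid's first-pass vp is leakage-corrected, so its fixed-vp")
print("refit recovers a less biased Ktrans.")
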