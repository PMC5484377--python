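# dcehybrid

Quantifying **subtle blood–brain-barrier (BBB) permeability** from
T1-weighted dynamic contrast-enhanced (DCE) MRI is hard: in
normal-appearing white matter the leaked tracer is a tiny fraction of the
intravascular signal, so conventional curve fitting suffers from noise,
parameter covariance and bias from ignored backflux. `dcehybrid`
implements a three-step **first-pass / Patlak-plot hybrid estimator** of
the volume transfer constant K^trans (min⁻¹) and the fractional plasma
volume v_p, together with ΔR1 mapping, four-colour white-matter
classification, and a Monte-Carlo simulation framework for validating
the estimator against the conventional Patlak plot.

It is aimed at researchers analysing high-temporal-resolution (~1 s)
low-dose brain DCE-MRI, and at anyone who wants a reproducible test bed
for low-permeability kinetic estimators.

## The model

The unidirectional two-compartment model gives the tissue concentration

```
C_t(t) = v_p C_p(t) + Ktrans ∫₀ᵗ C_p(τ) dτ
```

Dividing by C_p(t) yields the Patlak plot: v_d(t) = C_t/C_p against
*concentration-stretched time* t_stretch = ∫C_p/C_p, a line with slope
K^trans and intercept v_p. Real tissue also lets tracer flow back
(modified Tofts model, backflux rate k_ep = K^trans/v_e), which bends the
plot down: Patlak then overestimates v_p and underestimates K^trans.

The hybrid estimator runs three steps:

1. conventional Patlak fit on t_stretch ∈ [85, 250] s → initial K^trans;
2. leakage-corrected first-pass v_p: subtract the interstitial component
   `Ktrans ∫C_p` implied by step 1, then `v_p = ∫_w C_iv / ∫_w C_p` over
   the first-pass window w (very insensitive to step-1 errors, because
   the intravascular signal dominates the first pass);
3. Patlak refit with v_p fixed at the step-2 value → final K^trans.

ΔR1 = R1_post − R1_N (from the SPGR signal model, frame-averaged) maps
residual contrast voxelwise; white matter is partitioned into blue /
green / red / yellow regions by ΔR1 and first-pass v_p thresholds, and
ROI-averaged curves from those regions feed the kinetic fits.

## Worked example

```
$ python examples/fit_roi_curve.py
truth        Ktrans = 0.0074 /min   vp = 0.0240
Patlak       Ktrans = 0.0068 /min   vp = 0.0249   (r2 = 0.99971)
hybrid       Ktrans = 0.0071 /min   vp = 0.0241
hybrid step1 Ktrans = 0.0068 /min   vp = 0.0249
```

A noiseless white-matter-like curve (modified Tofts, v_e = 0.20) is fitted
by both estimators. Backflux makes the conventional Patlak plot read the
plasma volume ~4% high and the transfer constant ~8% low; the hybrid
recovers v_p to a fraction of a percent and roughly halves the K^trans
bias. The other scripts in `examples/` demonstrate the Monte-Carlo noise
study, the ΔR1 colour classification on a phantom, the stability of the
estimators across t_stretch intervals, and the backflux sweep that
locates each estimator's failure point.

A thin CLI mirrors the library for batch use:

```
dcehybrid fit-roi --curves ct.csv --aif cp.csv --method hybrid --interval 85:250
dcehybrid simulate-mc --method both --reps 200 --seed 1 --out pd_table.csv
dcehybrid map-dr1 --dynamic dyn.nii.gz --r1n r1n.nii.gz --m0 m0.nii.gz
```

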