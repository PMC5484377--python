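# Methods

## Signal model

All signal↔relaxation conversions use the steady-state spoiled
gradient-echo (SPGR) equation
`S = M0 sin α (1−E1)/(1−cos α E1)`, `E1 = exp(−TR·R1)`.
Native R1 and M0 come from a variable-flip-angle fit (α = 2°, 8°, 15°,
20° by default), initialised with the classic `S/sin α` vs `S/tan α`
linearisation and refined by Levenberg–Marquardt. The dynamic sequence's
TR and flip angle are configuration parameters with defaults TR = 5 ms
and α = 20° (the dynamic series repeats the fourth VFA sequence).

Post-injection R1 uses the *subtraction* convention: the measured
enhancement `SI_post − SI_pre` is added to the model-predicted native
signal before inversion, cancelling static offsets between the measured
baseline and the VFA-derived scale. The scalar path inverts by bracketed
root finding on [1e-4, 50] s⁻¹ (the SPGR signal is strictly monotone in
R1, so the root is unique); the vectorised map/Monte-Carlo path uses the
equivalent closed form `E1 = (M0 sin α − S)/(M0 sin α − S cos α)`, and
the two are tested to agree to 1e-10. Signals outside the attainable
range (0, M0 sin α) have no solution and become NaN (counted) on map
paths. Concentration is linear in the rate change: `C = ΔR1 / r1` with
r1 = 4.39 mM⁻¹s⁻¹ by default.

Negative ΔR1 and negative concentrations are deliberately propagated,
never clipped — roughly a fifth of white-matter voxels in this kind of
data show negative ΔR1, and clipping would bias every ROI average.

## Kinetic models and units

K^trans and k_ep are stored in min⁻¹ (the reporting convention) and
converted to s⁻¹ only at integration boundaries. The unidirectional
model uses a cumulative trapezoid; the modified Tofts model evaluates
the exponential-kernel convolution with an exact per-segment recursion
for piecewise-linear C_p (`I_{n+1} = I_n e^{−a} + dt[c_n f1(a) +
c_{n+1} f2(a)]`, with series guards below a = 1e-6), which is exact for
linear segments and therefore stable at the coarse 1.03 s sampling and
the small k_ep of white matter. Halving dt changes forward outputs by
< 0.1%.

Stretched time divides the cumulative plasma integral by the
instantaneous plasma concentration; samples where the baseline-subtracted
C_p falls below 5% of its peak are masked (the ratio diverges at
baseline). Patlak fits are unweighted OLS over the masked points whose
t_stretch lies in the (inclusive) fitting interval; the fixed-v_p
variant solves the one-parameter least-squares problem
`Ktrans = Σx(y−vp)/Σx²`. Negative fitted values are reported as-is.

## First-pass window and the hybrid

Bolus arrival is the first sample above baseline mean + 5 baseline SDs
(with a tiny absolute guard for noiseless curves); the window ends at
the first local minimum after the global peak — the valley between first
pass and recirculation — falling back to a 40%-of-peak decay threshold
for bump-free curves. Both rules are config-overridable.

The leakage-corrected v_p subtracts `Ktrans ∫C_p` from the tissue curve
before taking the first-pass integral ratio. This decomposition into
intravascular and interstitial components is reconstructed from the
method's description (the original appendix equations are not available
in the source text we had); it is the minimal construction with the
documented properties: it reduces to the uncorrected ratio at
Ktrans = 0, is exact on unidirectional data with the true Ktrans, and a
±50% error in the supplied Ktrans moves v_p by well under 5% at
white-matter-scale parameters (tested). An experimental alternating
estimator (`fp_simul`) that iterates the v_p and Ktrans stages to a
fixed point is provided for comparison but is not on the hybrid path.

Step 1 of the hybrid always fits t_stretch 85–250 s even when the Step-3
interval is swept (85–250 is the method's fixed initialisation window;
interval-stability analyses vary only the refit). A preset for the
80–250 s variant that appears alongside 85–250 in the literature is
included; 85–250 is the default. If Step 1 returns a negative Ktrans the
correction proceeds with it unchanged and the result carries a flag.

## ΔR1 mapping and colour classification

SI_pre is the baseline-frame mean and SI_post the mean of the last 10
frames (~4.5 min post injection); frame averaging suppresses Rician
noise before inversion. The four-colour partition is

| label  | criteria                              |
|--------|----------------------------------------|
| blue   | ΔR1 ≤ 0 or v_p ≤ 0.01                  |
| green  | 0 < ΔR1 < 0.012 and v_p > 0.01         |
| red    | 0.012 ≤ ΔR1 < 0.025 and v_p > 0.01     |
| yellow | ΔR1 ≥ 0.025 and v_p > 0.01             |

with ΔR1 in s⁻¹ and v_p the *uncorrected* first-pass estimate. The
boundary cases ΔR1 = 0 and v_p = 0.01, which the strict inequalities
above would leave unclassified, are assigned to blue so the partition is
exhaustive; NaN inputs get a 255 sentinel. White-matter masks use a
strict probability threshold (> 0.95). CoV is sample SD (n−1) over mean.
ANOVA/Tukey regional comparisons are a thin wrapper over
`scipy.stats.f_oneway`/`tukey_hsd` for user-supplied data.

## Synthetic plasma input (AIF)

The simulation's plasma curve is **synthetic** — a gamma-variate first
pass (unit-peak shape `(s/tp)^α e^{α(1−s/tp)}`), a delayed broader
gamma-variate recirculation bump, and a washout tail
`a_tail (1−e^{−s/12})e^{−s/800}` — because no measured samples of the
original superior-sagittal-sinus curve are available. Its defaults were
calibrated once, against published anchors of the study it emulates and
nothing else:

* shape: a single global peak, an inter-pass valley, a recirculation
  bump, zero during the 33 baseline frames, arrival ~6 s after
  injection;
* stretched-time geometry: t_stretch ≈ 80 s at the end of the first
  pass (~33 s post injection) and ≈ 250 s at 157 s post injection, with
  an approximately linear stretch/lab relation in between (this
  correspondence is only internally consistent if the published lab
  axis is measured from injection, which is how we read it);
* amplitude: with the truth parameters (below), the last-10-frame ΔR1
  of the synthetic tissue curve equals ≈ 0.0386 s⁻¹, the reported
  late-enhancement level of the high-ΔR1 white-matter region the
  simulation is meant to resemble. The resulting first-pass peak is
  ≈ 1.3 mM, plausible for a compact 3 ml low-dose bolus read in a large
  vein.

What the generator does **not** emulate: measurement noise on C_p (the
study treats the plasma curve as fixed), dispersion/delay between vessel
and tissue, inflow artefacts, patient-specific AIF variability. Passing
simulation tests therefore demonstrates estimator properties *given* a
well-behaved input function, not robustness to AIF measurement error.

## Monte-Carlo study

Defaults mirror the study conditions: truths K^trans = 0.0074 min⁻¹,
v_e = 0.20, v_p = 0.024; 300 frames at Δt = 1.03 s with 33 baseline
frames and baseline signal 470; relaxivity 4.39 mM⁻¹s⁻¹; native
R1₀ = 1/0.6 s⁻¹ (typical 1.5 T white matter; the source does not print
its T10); Rician noise at 1–5% of baseline
(`sqrt((S+g1)² + g2²)`, σ = level × baseline mean). Each repetition
averages `n_average` noisy signal curves (default 100, emulating an ROI
average), inverts frame-wise to concentration with the same signal model
used for synthesis (the "known native R1" convention), and fits both
estimators. Percent deviation is (measured − true)/true; fit failures
are excluded and counted.

The default preset is 200 repetitions of 100-curve averages — the
averaged-scheme arm of the study — which keeps a full noise sweep under
a few seconds; `--full` on the CLI switches to the 20 000-repetition
single-curve arm. Randomness flows from one master seed through spawned
substreams per noise level, so results are bit-reproducible and
independent of sweep order.

With these conditions the zero-noise backflux biases land at
Patlak +3.8% (v_p) / −8.1% (K^trans) and hybrid +0.6% / −4.7%, and the
4%-noise averaged-scheme PD means at Patlak ≈ +3.6 / −8.2 and
hybrid ≈ +0.4 / −4.9 — the bias ordering and magnitudes the estimator
comparison is built around (the acceptance script recomputes these at
run time). The PD *spreads* come out some 40–50% larger than the
published SDs for three of four cells; the spread scale is set by the
signal-to-concentration sensitivity, which depends on the unpublished
T10 and C_p amplitude, and we chose both on physical grounds rather
than adjusting them to the published SDs. The hybrid's spread remains
below Patlak's at every noise level, which is the comparison the study
turns on.

## Numerical choices and degenerate inputs

* VFA fit: linearised start + bounded least squares, xtol/ftol 1e-14;
  all-zero signals raise a fit failure.
* SPGR inversion: brentq xtol 1e-10 (scalar); closed form (vector).
* Curves must be strictly increasing, uniformly sampled; mismatched
  grids raise alignment errors rather than silently resampling.
* CoV is undefined (raises) within 1e-12 of a zero mean.
* Flat plasma curves raise no-bolus / empty-series errors; fitting
  windows with fewer than the minimum points raise insufficient-data
  errors tagged with the hybrid stage that failed.

## Limitations

* The leakage-correction construction and the first-pass window rules
  are reconstructions of a partially documented procedure (see above).
* No B1-inhomogeneity correction, T2*/water-exchange effects, AIF
  dispersion or bolus-arrival fitting: out of scope.
* Voxelwise hybrid mapping works but is not optimised for whole-brain
  throughput; the intended unit of analysis is the ROI-averaged curve.
* In vivo regional values (patient tables, the ΔR1–K^trans regression
  R² ≈ 0.99) require patient data; the package covers those code paths
  with synthetic phantoms only.
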