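"""Monte-Carlo accuracy/precision comparison at 4% Rician noise.

Each repetition averages 100 simulated noisy signal curves (mimicking an
ROI average over ~100 white-matter voxels), inverts them to
concentration and fits both estimators; 200 repetitions give the mean
(accuracy) and SD (precision) of the percent deviation from truth.
"""

from dcehybrid import SimConfig, monte_carlo_pd

cfg = SimConfig(seed=1)  # 200 reps x 100-curve averages by default

print("4% Rician noise, 100-curve SI averaging, 200 repetitions")
print(f"{'method':8s} {'param':7s} {'mean PD %':>10s} {'SD PD %':>9s}")
for method in ("patlak", "hybrid"):
    for s in monte_carlo_pd(cfg, method, noise_levels=(0.04,)):
        print(f"{method:8s} {s.param:7s} {100 * s.mean_pd:>+10.2f} {100 * s.sd_pd:>9.2f}")

print()
print("The mean PD is the backflux-induced bias (noise barely moves it);")
print("the SD is the noise-induced spread. The hybrid roughly halves the")
print("Ktrans bias and cuts the vp spread several-fold relative to Patlak.")
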