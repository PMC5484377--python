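"""Where does each estimator fail as backflux grows?

Sweeps the true Ktrans from 0.004 to 0.035 min^-1 (kep = Ktrans/ve, so
higher Ktrans means proportionally more backflux) at a fixed 4% noise
with SI averaging, and reports the mean Ktrans PD per method. The
conventional Patlak plot degrades first; the hybrid tolerates roughly
50% more backflux before its bias passes -20%.
"""

from dcehybrid import SimConfig, ktrans_sweep

cfg = SimConfig(seed=7, n_reps=60)
df = ktrans_sweep(cfg)

table = df[df.param == "ktrans"].pivot_table(
    index="true_ktrans", columns="method", values="mean_pd"
)
print("mean Ktrans PD (%) by true Ktrans (min^-1):")
print((100 * table).round(1))
for method in ("patlak", "hybrid"):
    crossed = table[table[method] < -0.20]
    where = f"{crossed.index.min():.3f}" if len(crossed) else "beyond grid"
    print(f"{method}: PD first passes -20% at true Ktrans = {where}")
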