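"""Minimum-p dichotomization and the penalized-Cox scenario grid.

A synthetic cohort of 300 patients is generated whose hazard triples above
the midpoint of a scaled measure.  The minimum-p-value search over 30
candidate thresholds recovers the planted cutpoint; the scenario grid then
fits ridge-penalized Cox models (continuous and discretized, original and
TIL-fraction-adjusted) and ranks measures by Harrell's concordance.
"""

import numpy as np
import pandas as pd
import tilscape as ts

rng = np.random.default_rng(5)
n = 300
meas = pd.DataFrame({
    "patient_id": [f"P{i:04d}" for i in range(n)],
    "m": rng.uniform(0, 1, n),
    "pct_tils": rng.uniform(0, 1, n),
})
spec = ts.CohortSpec(n_patients=n, driver_measure="m", beta=np.log(3.0),
                     threshold_effect=True, threshold=0.5, seed=11)
clin = ts.generate_cohort(spec, meas)
df = meas.merge(clin, on="patient_id")
df["cancer_type"] = "sim"
df["scale"] = "binary"

scaled = ts.minmax_scale(df["m"].to_numpy())
thr, labels, curve = ts.minp_dichotomize(
    scaled, df["OS.time"].to_numpy(), df["OS"].to_numpy(), df["age"].to_numpy()
)
best_p = curve["p"].min()
print(f"true cutpoint 0.50 -> recovered {thr:.3f} (min p = {best_p:.2e}, "
      f"{len(curve)} candidates)")

results = ts.run_all_scenarios(df, measures=["m"])
cols = ["endpoint", "model", "measure_scale", "hazard_ratio", "p_value", "c_index"]
print("\nscenario grid (binary map scale):")
print(results[cols].round(4).to_string(index=False))

km = ts.km_curves(df["OS.time"].to_numpy(), df["OS"].to_numpy(), labels)
print(f"\nlog-rank p between min-p groups: {km['logrank_p']:.2e}")
print("Discretized scenarios reach lower p than the continuous ones here —")
print("the planted effect really is a step, and the min-p search finds it.")
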