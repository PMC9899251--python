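"""End-to-end comparison: calorimeter dose vs chamber-derived dose per field.

For six synthetic fields, the calorimeter dose comes from analysing a 20-run
trace series; the chamber dose is simulated with a 4.5% systematic
overestimate (an over-applied recombination correction).  The comparison
reports per-field ratios and the mean ratio with its Type A SE.
"""
import numpy as np

from flashcal import (
    TraceRecipe,
    aggregate_runs,
    analyze_trace,
    gen_run_series,
    ratio_summary,
    ratio_to_calorimeter,
)

fields = ["5x6", "5x8", "5x10", "5x12", "6x5", "12x5"]
rng = np.random.default_rng(2)

ratios = {}
for i, field in enumerate(fields):
    runs = gen_run_series(TraceRecipe(), n_runs=20, inter_run_rel_sd=1.8e-3, seed=100 + i)
    d_cal = aggregate_runs([analyze_trace(tr).dose_to_water for tr, _ in runs]).mean
    d_chamber = 7.8 * 1.045 * (1 + 2e-3 * rng.standard_normal())  # chamber chain, biased high
    ratios[field] = ratio_to_calorimeter(d_cal, d_chamber)

for field, r in ratios.items():
    print(f"field {field:<6} calorimeter/chamber = {r:.4f}")
mean, se = ratio_summary(list(ratios.values()))
print(f"mean ratio = {mean:.4f} +/- {se:.4f} (Type A SE over {len(ratios)} fields)")
# A mean ratio below 1 means the chamber chain overestimates the dose here
# by ~4.5%, the signature of an overestimated ion-recombination correction.
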