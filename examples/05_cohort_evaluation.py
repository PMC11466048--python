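"""Evaluate feature sets on a synthetic graded cohort.

Generates arteries with arteriosclerosis-like grades 0-3 (diffuse plus
focal luminal narrowing, log-normal size nuisance), extracts features,
and compares area-based against thickness-based feature sets: per-feature
Kendall tau-b association with the grade and ridge-regression R2 per
feature subset.
"""

from arterymetrics.evaluate import feature_score_associations, ridge_r2
from arterymetrics.simulate import make_cohort

cohort = make_cohort(n_arteries=40, seed=11)

assoc = feature_score_associations(
    cohort, ["intima_area", "intima_average", "ratio_average", "ratio_peak_height"]
)
print("Kendall tau-b vs grade:")
for _, row in assoc.iterrows():
    print(f"  {row['feature']:18s} tau={row['tau']:+.2f}  p={row['p_value']:.2g}")

print("\nridge R2 by feature subset:")
for subset in ("area_only", "thickness_only", "combined"):
    print(f"  {subset:15s} {ridge_r2(cohort, subset):.3f}")

print("\nThickness-based features outrank the area baseline: they carry")
print("the normalized diffuse signal and the focal peaks that raw areas")
print("dilute or miss.")
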