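"""Simulate a three-group cohort and reproduce the group-level statistics.

Generates 33 synthetic biopsy scans (11 active EoE, 11 inactive EoE, 11
non-EoE controls) with planted group effects, processes each through the
morphometry pipeline, and runs ANOVA + Tukey, Spearman correlations against
the histology scores, and ROC analysis of the mean pore area.

Runtime: about two minutes.
"""

import pandas as pd

import shgmorph as sm
from shgmorph.stats import run_cohort_analysis, scores_to_frame

config = sm.CohortConfig(image_size=256, seed=0)
samples, scores = sm.generate_cohort(config)

rows = []
for sample in samples:
    summary = sm.summarize_sample(sample.scan, sample.roi)
    rec = {"sample_id": sample.sample_id, "group": sample.sample_id.rsplit("_", 1)[0]}
    rec.update(summary.to_dict())
    rows.append(rec)
results = pd.DataFrame(rows)

report = run_cohort_analysis(results, scores_to_frame(scores))

print("group means:")
print(
    results.groupby("group")[
        ["mean_fiber_width_um", "mean_pore_area_um2", "pore_density_per_mm2"]
    ].mean().round(2)
)
pore = next(c for c in report.comparisons if c.metric == "mean_pore_area_um2")
print("\nTukey-adjusted p, mean pore area:")
for pair, p in pore.pairwise_p.items():
    print(f"  {pair[0]} vs {pair[1]}: p = {p:.4f}")

corr = report.correlations.set_index(["metric", "score"])
print("\nSpearman r vs histology:")
for metric in ("mean_pore_area_um2", "pore_density_per_mm2", "mean_fiber_width_um"):
    r_pec = corr.loc[(metric, "pec"), "r"]
    r_lpf = corr.loc[(metric, "lpf"), "r"]
    print(f"  {metric}: r(PEC) = {r_pec:+.2f}, r(LPF) = {r_lpf:+.2f}")

print("\nROC of mean pore area:")
print(report.rocs_frame().round(2).to_string(index=False))
# Expected: enlarged pores in active EoE (~50 vs ~33 um^2), pore area
# correlating positively and pore density negatively with eosinophil counts
# and fibrosis grade, and a pore-area threshold near 43 um^2 separating
# active from inactive disease with high specificity.
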