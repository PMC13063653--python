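"""Cohort statistics: dental vs skeletal midline deviation.

Generates a 66-subject cohort, computes per-subject profiles from the
model-estimated true landmark positions, and reports medians/IQRs, the
paired Wilcoxon comparison of the dental-midline and skeletal-midline
deviations, and their Spearman correlation.
"""

from dentasym import (
    SyntheticConfig,
    estimate_true_positions,
    generate,
    run_cohort_analysis,
)
from dentasym.reliability import profiles_table, true_position_records

records, truth = generate(SyntheticConfig(n_subjects=66, seed=7))
estimates = estimate_true_positions(records)
profiles = profiles_table(true_position_records(estimates, group="A"))
result = run_cohort_analysis(profiles, compared_group="A")

print("group A summaries (median [IQR] (range), mm or deg):")
for s in result.summaries:
    print(
        f"  {s.parameter:>24s}: {s.median:+5.2f} [{s.iqr:.2f}] "
        f"({s.range_min:+.2f} .. {s.range_max:+.2f})"
    )

c = result.comparison
print(
    f"\nWilcoxon dentMid_facMP vs maxMP_facMP_at_dentMid: p = {c.p_value:.3f}, "
    f"HL difference = {c.median_difference_estimate:+.2f} mm "
    f"(95% CI {c.ci95[0]:+.2f} .. {c.ci95[1]:+.2f})"
)
print(f"Spearman r = {result.spearman_r:.2f}")

# A strong correlation with a small paired difference means dental-midline
# deviations in this cohort mostly track the skeletal midline rather than
# arising from tooth migration — the generator built them that way.
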