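"""Compare the degree of instability across cancer types.

Scores a simulated cohort, keeps the MSI-H samples, and runs one-way ANOVA
with Tukey HSD on their scores by cancer type; colon cancers carry a
higher instability burden than endometrial cancers.
"""

from msiscore import (ScoringConfig, SimulationConfig, compare_groups,
                      score_cohort, simulate_cohort)

cohort, _ = simulate_cohort(SimulationConfig(seed=13))
scored = score_cohort(cohort, cohort.locus_ids, ScoringConfig(cutoff=10.0))
msih = scored["status"] == "MSI-H"

groups = {
    ct: scored.loc[msih & (cohort.cancer_type == ct), "msi_score"]
    for ct in ("COAD", "STAD", "UCEC")
}
res = compare_groups(groups)

print(f"ANOVA F = {res.f_statistic:.1f}, p = {res.p_value:.2e}")
for name, row in res.group_stats.iterrows():
    print(f"  {name}: n={row.n:3.0f}  mean MSI score {row['mean']:.1f} "
          f"(95% CI {row.ci_low:.1f}-{row.ci_high:.1f})")
for _, row in res.tukey.iterrows():
    print(f"  {row.group_a} vs {row.group_b}: "
          f"diff {row.mean_diff:+.1f}, Tukey p = {row.p_adj:.2e}")
# At the calibration conditions the colon-vs-endometrial difference is
# highly significant (p << 1e-5) while stomach sits in between - the MSI
# score quantifies a continuous degree of instability, not just a label.
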