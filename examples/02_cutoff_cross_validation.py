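"""Choose the MSS/MSI-H score cutoff by stratified fourfold CV.

Simulates a 294-sample cohort with the published class mix (dMMR/pMMR by
cancer type), then sweeps score thresholds on each training split and
reports the accuracy-optimal band and the chosen cutoff.
"""

from msiscore import (CVConfig, SimulationConfig, cross_validate_threshold,
                      simulate_cohort)

cohort, truth = simulate_cohort(SimulationConfig(seed=7))
result = cross_validate_threshold(cohort, cohort.locus_ids,
                                  cv_config=CVConfig(k=4, seed=7))

lo, hi = result.optimal_interval
print(f"samples               : {len(cohort)}")
print(f"optimal interval      : [{lo:.2f}, {hi:.2f}]")
print(f"chosen cutoff         : {result.chosen_cutoff}")
print(f"cross-validated acc.  : {result.overall_cv_accuracy:.3f}")
for fold in result.per_fold:
    print(f"  fold {fold.fold}: train-optimal "
          f"[{fold.interval[0]:.2f}, {fold.interval[1]:.2f}], "
          f"test accuracy {fold.test_accuracy:.3f}")
# At the default generative conditions the optimal band lands near 9.5-10
# with held-out accuracy around 0.98-1.00, which is why 10 is the standard
# 81-locus cutoff.
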