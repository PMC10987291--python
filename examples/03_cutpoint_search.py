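"""Constrained minimum-p cutpoint search on a simulated cohort.

A 400-patient cohort carries a planted hazard ratio of 3 for patients with
score above 0.25.  The search evaluates 50 equidistant thresholds over the
observed score range, keeps only splits leaving at least 15% of patients
in the smaller risk group, and picks the threshold with the minimum raw
log-rank p-value.
"""

from tmaquant import CohortConfig, cutpoint_search, generate_cohort, subgroup_km

cfg = CohortConfig(n_patients=400, hazard_ratio=3.0, true_cutpoint=0.25, seed=1)
cohort = generate_cohort(cfg)
print(f"cohort: {len(cohort)} patients, {int(cohort['event'].sum())} events")

result = cutpoint_search(cohort)
print(f"thresholds evaluated: {len(result.thresholds)} "
      f"({result.n_tests} admissible under the 15% rule)")
print(f"best threshold: {result.best_threshold:.4f} (planted: {cfg.true_cutpoint})")
print(f"raw log-rank p at best threshold: {result.best_p:.3g}")
print("note: minimum-p over a grid is anti-conservative; "
      f"the result records {result.n_tests} tests for that reason")

km = subgroup_km(cohort, result.best_threshold)
print(f"KM median, high-score group: {km.km_high.median:.1f} months")
print(f"KM median, low-score group:  {km.km_low.median:.1f} months")
# The selected threshold lands within one grid step of the planted cutpoint
# and the high-score group shows the shorter disease-free survival.
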