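"""Simulate a synthetic inpatient cohort and look at its shape.

The generator plants a known Bayesian network over admission-level traits
(sex, age, diagnosis, nursing-intensity group) and day-level contributing
factors, then samples whole hospital stays with per-day fall events.
"""

import fallnet as fn

config = fn.development_config(n_admissions=2000, seed=42)
cohort = fn.sample_cohort(config)

print(f"admissions:        {cohort.n_admissions}")
print(f"hospital days:     {cohort.total_hospital_days}")
print(f"falls:             {cohort.n_falls}")
print(f"falls/1000 days:   {cohort.fall_rate_per_1000():.2f} "
      f"(target {config.target_fall_rate})")

summary = fn.cohort_summary(cohort)
print(f"mean LOS:          {summary['length_of_stay']['mean']:.2f} days")
print("sex marginal:      "
      + ", ".join(f"{k}={v:.3f}" for k, v in summary["sex"].items()))
print("fallers:           "
      f"{summary['fall_events']['one']} once, "
      f"{summary['fall_events']['multiple']} more than once")
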