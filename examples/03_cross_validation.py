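"""Repeated 90/10 patient-level cross-validation of the full fit/predict loop.

Patients (not windows) are split, positives are oversampled in the training
folds only, and the four metrics are averaged over folds.
"""

import fallnet as fn
from fallnet.evaluation import cross_validate
from fallnet.learning import DirichletPrior
from fallnet.windowing import build_all_windows

cohort = fn.sample_cohort(fn.development_config(n_admissions=2000, seed=42))
windows = build_all_windows(cohort)
schema = fn.load_schema(fn.bundled_schema_path("development"))

report = cross_validate(schema, windows, DirichletPrior(n0=1.0), k=10, seed=0)
print(f"mean over {len(report.folds)} folds "
      f"({report.n_windows} scored windows):")
print(f"  AUC               {report.auc:.3f} (sd {report.sd['auc']:.3f})")
print(f"  error rate        {report.error_rate:.4f}")
print(f"  log loss          {report.log_loss:.4f}")
print(f"  spherical payoff  {report.spherical_payoff:.3f}")
print(f"  no-information    {report.no_information_rate:.4f}")
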