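"""Which variables explain the fall node? Entropy-reduction sensitivity.

Entropy reduction is the mutual information (in bits) between the fall node
and each other node, computed exactly from the fitted network; per-node
values are then summed by variable subgroup.
"""

import fallnet as fn
from fallnet.learning import DirichletPrior, fit_cpts
from fallnet.sensitivity import analyze
from fallnet.windowing import build_all_windows, oversample_positives

cohort = fn.sample_cohort(fn.development_config(n_admissions=2000, seed=42))
windows = oversample_positives(build_all_windows(cohort), seed=0)
schema = fn.load_schema(fn.bundled_schema_path("development"))
net = fit_cpts(schema, windows, DirichletPrior(n0=1.0))

report = analyze(net, target="fall", measure="entropy_reduction")
print("top variables by entropy reduction (bits):")
ranked = sorted(report.per_node.items(), key=lambda kv: -kv[1])
for name, value in ranked[:8]:
    print(f"  {name:22s} {value:.5f}")

print("\nsubgroup totals:")
for group, value in report.ranked_subgroups():
    print(f"  {group:22s} {value:.5f}")
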