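"""Two-site cohort comparison statistics from the packaged count tables.

The package ships the published summary counts of the two hospital cohorts;
every statistic (uncorrected Pearson chi-square, pooled two-sample t, rates
per 1000 hospital days) is recomputed from those counts.
"""

from fallnet.cohort_stats import compare_sites

out = compare_sites()

print("chi-square (site1 vs site2):")
for name, entry in out["chi_square"].items():
    print(f"  {name:22s} X2={entry['statistic']:10.2f} "
          f"df={entry['df']} p={entry['p']:.3g}")

print("\nlength of stay, pooled t:")
t = out["t_test"]["length_of_stay"]
print(f"  t={t['statistic']:.2f} df={t['df']:.0f} p={t['p']:.3g}")

print("\nrates per 1000 hospital days:")
for name, entry in out["rates"].items():
    chi = out["rate_chi_square"][name]
    print(f"  {name:22s} site1={entry['site1']:.2f} site2={entry['site2']:.2f} "
          f"X2={chi['statistic']:.2f} p={chi['p']:.3g}")
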