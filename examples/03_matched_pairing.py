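"""Matched-site pairing control and the aligned ±2 kb profile.

Each 5hmC-high site is paired with the nearest unused 5mC-high site from
the same exon status and sequence context, removing regional confounding;
the per-sample difference in mutated pair members is then tested.  The
aligned profile shows that the mutation-frequency difference is confined
to the modified position itself.
"""

import hydroxymut as hm

cohort = hm.simulate_cohort()
labels = hm.classify_sites(cohort.sites)
joins = hm.join_mutations_to_sites(cohort.sites, cohort.catalogs, ("C>T",))
exons = hm.merge_intervals(cohort.exons)

pairs = hm.pair_sites(cohort.sites, labels, exons, seed=1)
print(f"pairs: {len(pairs)}   unpaired 5hmC sites: {pairs.n_unpaired_hmc}")
q = pairs.pairs["distance"].quantile([0.25, 0.5, 0.75])
print(f"pair distance quartiles (bp): {q.to_dict()}")

df, p = hm.paired_comparison(pairs, joins, cohort.catalogs)
print(f"mean per-sample (mutated 5mC − mutated 5hmC) difference: "
      f"{df['diff'].mean():.1f}   signed-rank p = {p:.2e}")
# positive mean: mutations in paired 5mC sites exceed paired 5hmC sites

# the aligned profile needs spatially isolated modified sites; the dense
# default map (one CpG per ~100 bp) has none within a 2 kb radius, so use
# a sparse map where isolation is common
sparse = hm.simulate_cohort(hm.CohortSimConfig(seed=2, cpg_density=2e-4,
                                               baseline_mut_prob=5e-3))
s_labels = hm.classify_sites(sparse.sites)
s_joins = hm.join_mutations_to_sites(sparse.sites, sparse.catalogs, ("C>T",))
prof = hm.aligned_profile(sparse.sites, s_labels, s_joins, sparse.catalogs,
                          radius_bp=2000, bin_width_bp=500)
print("\nanchor-position mutation frequency (per anchor per sample):")
print(prof.anchors.to_string(index=False))
print("\nflanking-bin frequencies are orders of magnitude lower and "
      "indistinguishable between classes:")
print(prof.profile.groupby("site_class")["frequency"].mean())
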