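from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hydroxymut as hm
from hydroxymut import cohort_stats
from hydroxymut.cohort_stats import (compare_classes, class_fractions,
                                     expression_strata, pair_sites,
                                     paired_comparison, paired_signed_rank,
                                     threshold_sweep, tissue_ratio_correlation)
from hydroxymut.io_formats import IntervalSet
from hydroxymut.site_model import SampleCatalog
from conftest import toy_sites, toy_joins


def catalogs_for(sample_ids, assay="WGS", ages=None):
    return [SampleCatalog(sample_id=s, assay=assay,
                          age_years=None if ages is None else ages[i],
                          mutations=pd.DataFrame(
                              columns=["chrom", "pos", "ref", "alt"]))
            for i, s in enumerate(sample_ids)]


def fraction_table(mc, hmc):
    rows = []
    for i, (a, b) in enumerate(zip(mc, hmc)):
        rows.append((f"S{i}", "mc_high", 100, 0, a, False))
        rows.append((f"S{i}", "hmc_high", 100, 0, b, False))
    return pd.DataFrame(rows, columns=["sample_id", "site_class", "n_sites",
                                       "n_mutated", "fraction", "excluded"])


class TestClassFractions:
    def test_simple_fraction(self):
        sites = toy_sites([("chr1", i, "+", 0.9, 0.0) for i in range(10)])
        labels = hm.classify_sites(sites)
        joins = toy_joins([(0, "S", "C>T"), (3, "S", "C>T")])
        table = class_fractions(sites, labels, joins, catalogs_for(["S"]))
        row = table.set_index("site_class").loc["mc_high"]
        assert row["n_sites"] == 10 and row["fraction"] == 0.2

    def test_empty_catalog_gives_zero_fractions(self):
        sites = toy_sites([("chr1", i, "+", 0.9, 0.0) for i in range(5)])
        labels = hm.classify_sites(sites)
        table = class_fractions(sites, labels, toy_joins([]), catalogs_for(["S"]))
        assert (table.loc[table["site_class"] == "mc_high", "fraction"] == 0).all()

    def test_empty_class_flagged_excluded(self):
        sites = toy_sites([("chr1", i, "+", 0.9, 0.0) for i in range(5)])
        labels = hm.classify_sites(sites)  # no hmc_high at all
        table = class_fractions(sites, labels, toy_joins([]), catalogs_for(["S"]))
        assert table.set_index("site_class").loc["hmc_high", "excluded"]

    def test_matches_per_site_tally_on_toy(self):
        """Fractions equal a brute-force per-site loop on a 200-site toy."""
        rng = np.random.default_rng(8)
        sites = toy_sites([("chr1", i, "+", float(rng.random()),
                            float(rng.random())) for i in range(200)])
        labels = hm.classify_sites(sites)
        samples = ["A", "B", "C"]
        entries = [(int(rng.integers(0, 200)), rng.choice(samples), "C>T")
                   for _ in range(60)]
        table = class_fractions(sites, labels, toy_joins(entries),
                                catalogs_for(samples))
        for s in samples:
            hit = {i for i, sid, _ in entries if sid == s}
            for cls in ("mc_high", "hmc_high"):
                members = {i for i in range(200) if labels.iloc[i] == cls}
                expected = len(members & hit) / len(members)
                got = table.set_index(["sample_id", "site_class"]).loc[(s, cls), "fraction"]
                assert got == pytest.approx(expected)


class TestCompareClasses:
    def test_identical_fractions_degenerate(self):
        res = compare_classes(fraction_table([0.1] * 8, [0.1] * 8))
        assert res.p_value == 1.0 and res.reduction == 0 and res.degenerate

    def test_p_matches_exact_enumeration_n8(self):
        """Two-sided p equals exhaustive enumeration over all 2^8 sign
        assignments of the rank statistic."""
        rng = np.random.default_rng(4)
        d = rng.normal(0.02, 0.05, size=8)
        d = d[d != 0]
        p_pkg = paired_signed_rank(d, "two-sided")
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        w_all = [np.sum(ranks[list(signs)]) for signs in
                 (np.array(c, bool) for c in product([0, 1], repeat=len(d)))]
        w_all = np.array(w_all)
        mean_w = len(d) * (len(d) + 1) / 4
        p_exact = np.mean(np.abs(w_all - mean_w) >= abs(w_obs - mean_w) - 1e-12)
        assert p_pkg == pytest.approx(p_exact, abs=1e-10)

    def test_label_swap_flips_effect_and_preserves_p(self):
        rng = np.random.default_rng(9)
        mc = rng.uniform(0.01, 0.1, 12)
        hmc = rng.uniform(0.01, 0.1, 12)
        a = compare_classes(fraction_table(mc, hmc))
        b = compare_classes(fraction_table(hmc, mc))
        assert a.p_value == pytest.approx(b.p_value)
        assert (a.mean_mc - a.mean_hmc) == pytest.approx(-(b.mean_mc - b.mean_hmc))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 6 samples"):
            compare_classes(fraction_table([0.1] * 5, [0.2] * 5))

    def test_detects_injected_excess(self, default_analysis):
        """On the default cohort (methylated ~2x more mutable) the
        estimated reduction tracks the ledger and is highly significant."""
        cohort, labels, joins = default_analysis
        table = class_fractions(cohort.sites, labels, joins, cohort.catalogs)
        res = compare_classes(table)
        assert res.p_value < 1e-6
        assert res.reduction == pytest.approx(cohort.truth.realized_reduction, abs=0.1)


class TestThresholdSweep:
    def test_default_cell_consistent_with_compare_classes(self, small_analysis):
        cohort, labels, joins = small_analysis
        table = class_fractions(cohort.sites, labels, joins, cohort.catalogs)
        expected = compare_classes(table, "greater").p_value
        p_right, p_left = threshold_sweep(cohort.sites, joins, cohort.catalogs,
                                          [0.3], [0.5])
        assert p_right.loc[0.3, 0.5] == pytest.approx(expected)

    def test_all_zero_hmc_rel_leaves_cells_missing(self):
        sites = toy_sites([("chr1", i, "+", 0.9, 0.0) for i in range(50)])
        p_right, _ = threshold_sweep(sites, toy_joins([]), catalogs_for(list("ABCDEFG")),
                                     [0.2, 0.3], [0.5, 0.7])
        assert p_right.isna().all().all()

    def test_effect_direction_stable_across_cells(self, small_analysis):
        """With a one-sided injected effect the right-tail cell p-values
        dominate the left-tail ones everywhere."""
        cohort, labels, joins = small_analysis
        p_right, p_left = threshold_sweep(cohort.sites, joins, cohort.catalogs,
                                          [0.2, 0.3], [0.5, 0.7])
        ok = p_right.notna()
        assert (p_right[ok] < p_left[ok]).all().all()


class TestExpressionStrata:
    @staticmethod
    def genes(medians):
        df = pd.DataFrame([("chr1", 100 * i, 100 * i + 50, f"g{i}")
                           for i in range(len(medians))],
                          columns=["chrom", "start", "end", "label"])
        return IntervalSet(df), pd.Series(medians, index=[f"g{i}" for i in range(len(medians))])

    def test_top_half_is_high(self):
        iv, med = self.genes([1, 2, 3, 4])
        high, low = expression_strata(iv, med)
        assert set(high.df["label"]) == {"g2", "g3"}

    def test_tie_rule_deterministic(self):
        iv, med = self.genes([5, 5, 5, 5])
        high1, _ = expression_strata(iv, med)
        high2, _ = expression_strata(iv, med)
        assert list(high1.df["label"]) == list(high2.df["label"]) == ["g0", "g1"]

    def test_odd_count_sizes_differ_by_at_most_one(self):
        iv, med = self.genes([1, 2, 3, 4, 5])
        high, low = expression_strata(iv, med)
        assert abs(len(high) - len(low)) <= 1
        assert len(high) + len(low) == 5


class TestPairing:
    def test_nearest_eligible_respects_exon_status(self):
        sites = toy_sites([("chr1", 100, "+", 0.9, 0.9),   # hmc, exonic
                           ("chr1", 90, "+", 0.9, 0.0),    # mc, exonic
                           ("chr1", 95, "+", 0.9, 0.0)])   # mc, intronic
        labels = hm.classify_sites(sites)
        # exons cover 90 and 100 but not 95: the nearer intronic mc loses
        exons = IntervalSet(pd.DataFrame([("chr1", 96, 102, ""), ("chr1", 88, 92, "")],
                                         columns=["chrom", "start", "end", "label"]))
        pairs = pair_sites(sites, labels, exons, seed=0)
        assert len(pairs) == 1
        assert pairs.pairs.iloc[0]["mc_index"] == 1  # exonic mc at 90, not intronic 95

    def test_exclusive_matching_under_competition(self):
        sites = toy_sites([("chr1", 100, "+", 0.9, 0.9),
                           ("chr1", 104, "+", 0.9, 0.9),
                           ("chr1", 102, "+", 0.9, 0.0)])
        labels = hm.classify_sites(sites)
        pairs = pair_sites(sites, labels, None, seed=0)
        assert len(pairs) == 1 and pairs.n_unpaired_hmc == 1

    def test_seed_reproducibility_and_count_invariance(self):
        rng = np.random.default_rng(14)
        rows = []
        for i, p in enumerate(np.sort(rng.choice(5000, 80, replace=False))):
            rows.append(("chr1", int(p), "+", 0.9, 0.9 if i % 2 else 0.0))
        sites = toy_sites(rows)
        labels = hm.classify_sites(sites)
        a = pair_sites(sites, labels, None, seed=5)
        b = pair_sites(sites, labels, None, seed=5)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)
        counts = {len(pair_sites(sites, labels, None, seed=s)) for s in range(6)}
        assert len(counts) == 1  # equal numbers of both classes: all pair

    def test_output_is_a_matching(self, small_analysis, merged_exons):
        cohort, labels, _ = small_analysis
        pairs = pair_sites(cohort.sites, labels, merged_exons, seed=1)
        assert pairs.pairs["mc_index"].is_unique
        assert pairs.pairs["hmc_index"].is_unique
        assert not set(pairs.pairs["mc_index"]) & set(pairs.pairs["hmc_index"])

    def test_no_mc_sites_rejected(self):
        sites = toy_sites([("chr1", 100, "+", 0.9, 0.9)])
        labels = hm.classify_sites(sites)
        with pytest.raises(ValueError, match="no mc_high"):
            pair_sites(sites, labels, None, seed=0)


class TestPairedComparison:
    def test_no_mutations_gives_p_one(self):
        sites = toy_sites([("chr1", 10, "+", 0.9, 0.9), ("chr1", 20, "+", 0.9, 0.0)])
        labels = hm.classify_sites(sites)
        pairs = pair_sites(sites, labels, None, seed=0)
        df, p = paired_comparison(pairs, toy_joins([]), catalogs_for(list("ABCDEF")))
        assert p == 1.0 and (df["diff"] == 0).all()

    def test_matches_direct_tally_on_50_pairs(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(100):
            rows.append(("chr1", 10 * i, "+", 0.9, 0.9 if i % 2 else 0.0))
        sites = toy_sites(rows)
        labels = hm.classify_sites(sites)
        pairs = pair_sites(sites, labels, None, seed=0)
        assert len(pairs) == 50
        samples = ["A", "B"]
        entries = [(int(rng.integers(0, 100)), rng.choice(samples), "C>T")
                   for _ in range(40)]
        df, _ = paired_comparison(pairs, toy_joins(entries), catalogs_for(samples))
        for s in samples:
            hit = {i for i, sid, _ in entries if sid == s}
            exp = (len(hit & set(pairs.pairs["mc_index"]))
                   - len(hit & set(pairs.pairs["hmc_index"])))
            assert df.set_index("sample_id").loc[s, "diff"] == exp

    def test_injected_excess_shifts_differences_right(self, default_analysis,
                                                      default_cohort):
        cohort, labels, joins = default_analysis
        exons = hm.merge_intervals(cohort.exons)
        pairs = pair_sites(cohort.sites, labels, exons, seed=3)
        df, p = paired_comparison(pairs, joins, cohort.catalogs)
        assert df["diff"].mean() > 0 and p < 1e-6


class TestAlignedProfile:
    def test_isolated_anchor_zero_profile(self):
        sites = toy_sites([("chr1", 5000, "+", 0.9, 0.0),
                           ("chr1", 20000, "+", 0.9, 0.9)])
        labels = hm.classify_sites(sites)
        prof = hm.aligned_profile(sites, labels, toy_joins([]), catalogs_for(["S"]))
        assert (prof.profile["n_mutations"] == 0).all()
        assert prof.anchors.set_index("site_class").loc["mc_high", "n_anchors"] == 1

    def test_mutation_at_anchor_counts_only_there(self):
        sites = toy_sites([("chr1", 5000, "+", 0.9, 0.0)])
        labels = hm.classify_sites(sites)
        cat = SampleCatalog(sample_id="S", mutations=pd.DataFrame(
            [("chr1", 5000, "C", "T")], columns=["chrom", "pos", "ref", "alt"]))
        from hydroxymut.site_model import annotate_catalog
        annotate_catalog(cat)
        joins = toy_joins([(0, "S", "C>T")])
        prof = hm.aligned_profile(sites, labels, joins, [cat])
        assert (prof.profile["n_mutations"] == 0).all()
        assert prof.anchors.set_index("site_class").loc[
            "mc_high", "anchor_mutation_frequency"] == 1.0

    def test_matches_window_scan_oracle(self):
        """Profile counts equal a brute-force per-anchor scan on a toy."""
        rng = np.random.default_rng(6)
        anchor_pos = np.arange(10) * 10_000 + 5000
        sites = toy_sites([("chr1", int(p), "+", 0.9, 0.0 if i % 2 else 0.9)
                           for i, p in enumerate(anchor_pos)])
        labels = hm.classify_sites(sites)
        mut_pos = rng.integers(0, 100_000, 80)
        cat = SampleCatalog(sample_id="S", mutations=pd.DataFrame(
            [("chr1", int(p), "C", "T") for p in mut_pos],
            columns=["chrom", "pos", "ref", "alt"]))
        from hydroxymut.site_model import annotate_catalog
        annotate_catalog(cat)
        prof = hm.aligned_profile(sites, labels, toy_joins([]), [cat],
                                  radius_bp=2000, bin_width_bp=500)
        for cls in ("mc_high", "hmc_high"):
            anchors = [p for i, p in enumerate(anchor_pos)
                       if labels.iloc[i] == cls]
            got = prof.profile.loc[prof.profile["site_class"] == cls]
            for _, row in got.iterrows():
                expected = sum(
                    1 for a in anchors for m in mut_pos
                    if m != a and row["offset_lo"] <= m - a < row["offset_hi"])
                assert row["n_mutations"] == expected

    def test_no_isolated_anchors_rejected(self):
        sites = toy_sites([("chr1", 100, "+", 0.9, 0.0), ("chr1", 200, "+", 0.9, 0.9)])
        labels = hm.classify_sites(sites)
        with pytest.raises(ValueError, match="no isolated"):
            hm.aligned_profile(sites, labels, toy_joins([]), catalogs_for(["S"]))


class TestAgeCorrelation:
    def test_pearson_matches_closed_form(self):
        """r agrees with the textbook formula on 12 hand-enumerable points."""
        ages = np.array([30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85], float)
        counts = np.array([2, 3, 3, 5, 4, 6, 7, 6, 8, 9, 9, 11], float)
        sites = toy_sites([("chr1", i, "+", 0.9, 0.0) for i in range(1)])
        labels = hm.classify_sites(sites)
        cats = catalogs_for([f"S{i}" for i in range(12)], ages=list(ages))
        entries = []
        for i, c in enumerate(counts.astype(int)):
            entries += [(0, f"S{i}", "C>T")] * c
        # duplicate events at one site: emulate counts via join rows
        joins = toy_joins(entries)
        res = hm.age_correlation(cats, joins, labels)
        r_pkg = res.per_class.set_index("site_class").loc["mc_high", "pearson_r"]
        num = np.sum((ages - ages.mean()) * (counts - counts.mean()))
        den = np.sqrt(np.sum((ages - ages.mean()) ** 2)
                      * np.sum((counts - counts.mean()) ** 2))
        assert r_pkg == pytest.approx(num / den, abs=1e-12)

    def test_zero_age_variance_rejected(self):
        sites = toy_sites([("chr1", 0, "+", 0.9, 0.0)])
        labels = hm.classify_sites(sites)
        cats = catalogs_for([f"S{i}" for i in range(12)], ages=[50.0] * 12)
        with pytest.raises(ValueError, match="age variance"):
            hm.age_correlation(cats, toy_joins([]), labels)


class TestTissueRatio:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["tissue", "freq_modified",
                                           "freq_unmodified", "bulk_hmc"])

    def test_equal_frequencies_give_unit_ratio(self):
        t = self.table([(f"t{i}", 0.01, 0.01, 0.1 * i) for i in range(5)])
        res = tissue_ratio_correlation(t)
        assert (res.table["ratio"] == 1).all()

    def test_perfectly_linear_table(self):
        rows = [(f"t{i}", 0.01 * (5 - i), 0.01, i / 10) for i in range(5)]
        res = tissue_ratio_correlation(self.table(rows))
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.spearman_rho == pytest.approx(-1.0)

    def test_matches_hand_computation(self):
        rows = [("a", 0.02, 0.01, 0.30), ("b", 0.015, 0.01, 0.45),
                ("c", 0.012, 0.01, 0.50), ("d", 0.02, 0.02, 0.60),
                ("e", 0.008, 0.01, 0.80)]
        res = tissue_ratio_correlation(self.table(rows))
        ratio = np.array([2.0, 1.5, 1.2, 1.0, 0.8])
        bulk = np.array([0.30, 0.45, 0.50, 0.60, 0.80])
        assert res.pearson_r == pytest.approx(np.corrcoef(ratio, bulk)[0, 1])

    def test_zero_denominator_dropped_and_exclusion(self):
        rows = [("a", 0.02, 0.0, 0.3), ("b", 0.02, 0.01, 0.4),
                ("c", 0.015, 0.01, 0.5), ("d", 0.012, 0.01, 0.6),
                ("e", 0.01, 0.01, 0.7)]
        res = tissue_ratio_correlation(self.table(rows))
        assert res.dropped == ["a"]
        with pytest.raises(ValueError):
            tissue_ratio_correlation(self.table(rows), exclude=("b",))
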