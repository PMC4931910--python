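import numpy as np
import pandas as pd
import pytest

import hydroxymut as hm
from hydroxymut.glm import fit_poisson_glm, poisson_deviance
from hydroxymut.io_formats import IntervalSet
from hydroxymut.regional_model import (TrackSmoothingConfig, WindowSpec,
                                       build_window_table, cross_map_matrix,
                                       export_smoothed_tracks, fit_glm,
                                       gaussian_smooth, rank_predictors)
from conftest import toy_sites, toy_joins


def intervals(rows):
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def empty_intervals():
    return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "label"]))


class TestWindowTable:
    def test_gene_density_by_coverage(self):
        """Two genes totalling 50 kb inside a 100 kb window give density 0.5."""
        sites = toy_sites([("chr1", 10, "+", 0.9, 0.1)])
        genes = intervals([("chr1", 0, 30_000, "g1"), ("chr1", 50_000, 70_000, "g2")])
        spec = WindowSpec(window_size_bp=100_000, chrom_sizes={"chr1": 100_000})
        table = build_window_table(sites, toy_joins([]), [], genes,
                                   empty_intervals(), empty_intervals(),
                                   pd.Series({"g1": 1.0, "g2": 1.0}), spec)
        assert table.iloc[0]["gene_density"] == pytest.approx(0.5)

    def test_empty_window_excluded(self):
        sites = toy_sites([("chr1", 10, "+", 0.9, 0.1)])
        spec = WindowSpec(window_size_bp=100_000, chrom_sizes={"chr1": 200_000})
        table = build_window_table(sites, toy_joins([]), [], empty_intervals(),
                                   empty_intervals(), empty_intervals(),
                                   pd.Series(dtype=float), spec)
        assert not table.iloc[0]["excluded"] and table.iloc[1]["excluded"]

    def test_partial_terminal_window_kept_with_true_size(self):
        spec = WindowSpec(window_size_bp=100_000, chrom_sizes={"chr1": 150_000})
        w = spec.windows()
        assert list(w["end"] - w["start"]) == [100_000, 50_000]

    def test_window_size_floor(self):
        with pytest.raises(ValueError):
            WindowSpec(window_size_bp=500)

    def test_means_match_per_site_aggregation(self):
        """Window means equal a brute-force per-site loop on a 3-window toy."""
        rng = np.random.default_rng(12)
        rows = []
        for i in range(60):
            rows.append(("chr1", int(rng.integers(0, 30_000)), "+",
                         float(rng.random()), float(rng.random())))
        sites = toy_sites(rows)
        spec = WindowSpec(window_size_bp=10_000, chrom_sizes={"chr1": 30_000})
        joins = toy_joins([(int(i), "S", "C>T")
                           for i in rng.choice(60, 15, replace=False)])
        from hydroxymut.site_model import SampleCatalog
        cats = [SampleCatalog(sample_id="S", assay="WGS",
                              mutations=pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]))]
        table = build_window_table(sites, joins, cats, empty_intervals(),
                                   empty_intervals(), empty_intervals(),
                                   pd.Series(dtype=float), spec)
        for w in range(3):
            in_w = sites["pos"].between(w * 10_000, (w + 1) * 10_000 - 1)
            eligible = in_w & (sites["mod_level"] >= 0.10)
            if eligible.any():
                assert table.iloc[w]["mean_hmc"] == pytest.approx(
                    sites.loc[eligible, "hmc_level"].mean())
                assert table.iloc[w]["mean_hmc_rel"] == pytest.approx(
                    sites.loc[eligible, "hmc_rel"].mean())
            assert table.iloc[w]["mean_mod"] == pytest.approx(
                sites.loc[in_w, "mod_level"].mean())
            assert table.iloc[w]["eligible_cpg"] == int(in_w.sum())
            expected_muts = len({i for i in joins["site_index"]
                                 if in_w.iloc[i]})
            # joins may hit a site multiple times; here each site once
            assert table.iloc[w]["n_mutations"] == expected_muts


class TestGlmCore:
    @staticmethod
    def toy_table(n=50, seed=0, rate_fn=None):
        rng = np.random.default_rng(seed)
        x = rng.random(n)
        exposure = np.full(n, 2000.0)
        rate = rate_fn(x) if rate_fn else 0.002 * np.exp(1.5 * x)
        y = rng.poisson(exposure * rate)
        return pd.DataFrame({"x": x, "noise": rng.random(n), "n_mutations": y,
                             "exposure": exposure, "excluded": False})

    def test_intercept_only_d2_zero(self):
        t = self.toy_table()
        res = fit_poisson_glm(t["n_mutations"], np.empty((len(t), 0)), t["exposure"])
        assert res.d2 == 0.0

    def test_noiseless_predictor_saturates_d2(self):
        rng = np.random.default_rng(1)
        x = rng.random(200)
        exposure = np.full(200, 5e5)
        y = rng.poisson(exposure * 0.001 * np.exp(2 * x))
        res = fit_poisson_glm(y, x, exposure)
        assert res.d2 > 0.97

    def test_d2_matches_deviance_formula_oracle(self):
        """D² equals 1 − dev/dev_null with both deviances recomputed from
        2Σ[y log(y/μ) − (y − μ)] on a 20-window toy."""
        t = self.toy_table(n=20, seed=3)
        res = fit_glm(t, ["x"])
        mu = res.model.mu
        dev = poisson_deviance(t["n_mutations"], mu)
        mean_rate = t["n_mutations"].sum() / t["exposure"].sum()
        dev_null = poisson_deviance(t["n_mutations"], mean_rate * t["exposure"])
        assert res.residual_deviance == pytest.approx(dev, rel=1e-10)
        assert res.null_deviance == pytest.approx(dev_null, rel=1e-10)
        assert res.d2 == pytest.approx(1 - dev / dev_null, rel=1e-10)

    def test_exposure_offset_contract(self):
        """Doubling both counts and exposure leaves rate coefficients
        essentially unchanged."""
        t = self.toy_table(n=100, seed=5)
        a = fit_glm(t, ["x"])
        t2 = t.assign(n_mutations=t["n_mutations"] * 2, exposure=t["exposure"] * 2)
        b = fit_glm(t2, ["x"])
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=5e-3)

    def test_d2_invariant_under_affine_predictor_rescale(self):
        t = self.toy_table(n=80, seed=6)
        a = fit_glm(t, ["x"])
        t2 = t.assign(x=3.5 * t["x"] - 1.2)
        b = fit_glm(t2, ["x"])
        assert a.d2 == pytest.approx(b.d2, rel=1e-8)

    def test_constant_predictor_rejected(self):
        t = self.toy_table().assign(x=1.0)
        with pytest.raises(ValueError, match="constant predictor"):
            fit_glm(t, ["x"])


class TestRankPredictors:
    def test_duplicate_predictor_identical_d2(self):
        t = TestGlmCore.toy_table(n=80, seed=8)
        t["x_copy"] = t["x"]
        out = rank_predictors(t, ["x", "x_copy", "noise"])
        d2 = out.set_index("predictor")["d2_univariate"]
        assert d2["x"] == pytest.approx(d2["x_copy"], rel=1e-9)

    def test_cumulative_d2_non_decreasing(self):
        t = TestGlmCore.toy_table(n=80, seed=9)
        out = rank_predictors(t, ["x", "noise"])
        assert (np.diff(out["d2_cumulative"]) >= -1e-12).all()

    def test_true_driver_outranks_noise(self):
        """Across 100 seeds, the predictor that generated the response
        ranks above a pure-noise predictor in >= 95 of them."""
        wins = 0
        for seed in range(100):
            t = TestGlmCore.toy_table(n=100, seed=seed)
            out = rank_predictors(t, ["x", "noise"])
            wins += out.iloc[0]["predictor"] == "x"
        assert wins >= 95


class TestCrossMap:
    def test_identical_maps_identical_columns(self):
        rng = np.random.default_rng(2)
        maps = pd.DataFrame({"a": rng.random(60)})
        maps["b"] = maps["a"]
        counts = rng.poisson(50, 60)
        win = pd.DataFrame({"n_mutations": counts, "exposure": np.full(60, 1e4)})
        res = cross_map_matrix({"c1": win}, maps)
        assert res.d2.loc["c1", "a"] == pytest.approx(res.d2.loc["c1", "b"])
        assert res.degenerate_rows == ["c1"]

    def test_z_rows_standardised(self):
        rng = np.random.default_rng(3)
        maps = pd.DataFrame({k: rng.random(80) for k in "abc"})
        win = {f"c{i}": pd.DataFrame({
            "n_mutations": rng.poisson(40, 80), "exposure": np.full(80, 1e4)})
            for i in range(2)}
        res = cross_map_matrix(win, maps)
        np.testing.assert_allclose(res.z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(res.z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        maps = pd.DataFrame({"a": np.random.default_rng(0).random(10)})
        win = pd.DataFrame({"n_mutations": [1] * 9, "exposure": [100.0] * 9})
        with pytest.raises(ValueError, match="mismatch"):
            cross_map_matrix({"c": win}, maps)


class TestSmoothing:
    def test_constant_track_unchanged(self):
        cfg = TrackSmoothingConfig()
        out = gaussian_smooth(np.full(200, 3.7), cfg)
        np.testing.assert_allclose(out, 3.7, rtol=1e-12)

    def test_delta_spike_preserves_mass(self):
        cfg = TrackSmoothingConfig(n=21, sigma=2.0)
        x = np.zeros(200)
        x[100] = 5.0
        out = gaussian_smooth(x, cfg)
        assert out.sum() == pytest.approx(5.0, rel=1e-9)
        assert out[100] == out.max()

    def test_matches_direct_convolution_oracle(self):
        """Smoothing equals a brute-force per-position kernel sum on a
        60-window track, including edge renormalisation."""
        rng = np.random.default_rng(4)
        x = rng.random(60)
        cfg = TrackSmoothingConfig(n=11, sigma=2.5)
        k = cfg.kernel()
        out = gaussian_smooth(x, cfg)
        half = 5
        for i in range(60):
            num = den = 0.0
            for j in range(-half, half + 1):
                if 0 <= i + j < 60:
                    w = k[half + j]
                    num += w * x[i + j]
                    den += w
            assert out[i] == pytest.approx(num / den, rel=1e-10)

    def test_export_warns_on_short_chromosome(self, small_analysis):
        cohort, labels, joins = small_analysis
        spec = WindowSpec(window_size_bp=100_000, chrom_sizes={"chr1": 500_000})
        table = build_window_table(cohort.sites, joins, cohort.catalogs,
                                   cohort.genes, cohort.exons, cohort.cgi,
                                   cohort.expression_medians, spec)
        with pytest.warns(UserWarning, match="fewer windows"):
            tracks = export_smoothed_tracks(table, TrackSmoothingConfig(n=50))
        assert tracks.unsmoothed_chroms == ["chr1"]

    def test_smoothed_tracks_recover_injected_anticorrelation(self, default_cohort):
        """On the default cohort the smoothed 5hmC track anti-correlates
        with the smoothed mutation-frequency track."""
        cohort = default_cohort
        labels = hm.classify_sites(cohort.sites)
        joins = hm.join_mutations_to_sites(cohort.sites, cohort.catalogs, ("C>T",))
        spec = WindowSpec(window_size_bp=100_000,
                          chrom_sizes={"chr1": 5_000_000, "chr2": 5_000_000})
        table = build_window_table(cohort.sites, joins, cohort.catalogs,
                                   cohort.genes, cohort.exons, cohort.cgi,
                                   cohort.expression_medians, spec)
        tracks = export_smoothed_tracks(table, TrackSmoothingConfig(n=10, sigma=2.5))
        r = tracks.correlations["chr1"].loc["mutation_frequency", "mean_hmc_rel"]
        assert r < -0.3
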