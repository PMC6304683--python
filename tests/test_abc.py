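import numpy as np
import pandas as pd
import pytest
from scipy import stats

import demesweep as dw
from demesweep.abc import (
    AbcConfig,
    abc_reject,
    bayes_factor,
    compare_scenarios,
    marginal_density,
    posterior_pvalue,
    posterior_summaries,
    prune_correlated,
    regression_adjust,
    summarize,
)
from demesweep.simulate import DEFAULT_PRIORS

from conftest import make_panel, make_popmap


def _four_group_panel(seed=0, m=80, n=8):
    rng = np.random.default_rng(seed)
    blocks = []
    for k in range(4):
        p = rng.uniform(0.1, 0.9, size=m)
        blocks.append(rng.binomial(2, p[:, None], size=(m, n)))
    g = np.hstack(blocks).astype(np.int8)
    panel = make_panel(g)
    groups = {
        name: panel.samples[k * n:(k + 1) * n]
        for k, name in enumerate(["source", "early_colony", "colony_a", "colony_b"])
    }
    return panel, groups


class TestSummarize:
    def test_default_count_is_17(self):
        panel, groups = _four_group_panel()
        s = summarize(panel, groups, reference_group="source")
        assert len(s) == 17

    def test_identical_groups_fst_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, size=100)
        g = rng.binomial(2, p[:, None], size=(100, 120)).astype(np.int8)
        panel = make_panel(g)  # two groups drawn from identical frequencies
        groups = {"a": panel.samples[:60], "b": panel.samples[60:]}
        fst = dw.wc_fst(panel, groups["a"], groups["b"])[1]
        assert abs(fst) < 0.02

    def test_all_het_locus_value(self):
        # every individual heterozygous: p = 0.5, unbiased H = (2n/(2n-1)) * 0.5
        g = np.ones((5, 8), dtype=np.int8)
        panel = make_panel(g)
        groups = {"a": panel.samples[:4], "b": panel.samples[4:],
                  "c": panel.samples[:4], "d": panel.samples[4:]}
        s = summarize(panel, groups, reference_group="a")
        assert s["H_mean_a"] == pytest.approx((8 / 7) * 0.5)

    def test_monomorphic_group_sd_missing(self):
        g = np.zeros((10, 8), dtype=np.int8)
        g[:, 4:] = np.random.default_rng(1).integers(0, 3, size=(10, 4))
        panel = make_panel(g)
        groups = {"mono": panel.samples[:4], "poly": panel.samples[4:],
                  "x": panel.samples[4:], "y": panel.samples[4:]}
        s = summarize(panel, groups, reference_group="poly")
        assert np.isnan(s["H_sd_mono"])
        assert s["S_mono"] == 0


class TestPruneCorrelated:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
        df["dup"] = df["a"]
        kept = prune_correlated(df, rho_max=0.95)
        assert kept == ["a", "b", "c"]

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(500, 8)),
                          columns=[f"s{i}" for i in range(8)])
        kept = prune_correlated(df, rho_max=0.95)
        assert kept == list(df.columns)

    def test_negative_correlation_pruned(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.normal(size=200)})
        df["neg"] = -df["a"] + rng.normal(scale=1e-6, size=200)
        kept = prune_correlated(df, rho_max=0.95)
        assert kept == ["a"]


class TestAbcReject:
    def test_retained_count(self):
        rng = np.random.default_rng(6)
        sims = pd.DataFrame(rng.normal(size=(2000, 4)),
                            columns=list("abcd"))
        obs = pd.Series([0.0, 0.0, 0.0, 0.0], index=list("abcd"))
        kept, dist = abc_reject(obs, sims, AbcConfig(retain_fraction=0.005))
        assert len(kept) == 10
        assert np.all(np.diff(dist) >= 0)

    def test_observed_equal_to_sim_first(self):
        rng = np.random.default_rng(7)
        sims = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        obs = sims.iloc[137]
        kept, dist = abc_reject(obs, sims, AbcConfig(retain_fraction=0.01))
        assert kept[0] == 137
        assert dist[0] == pytest.approx(0.0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        sims = pd.DataFrame(rng.normal(size=(200, 5)),
                            columns=[f"s{i}" for i in range(5)])
        obs = pd.Series(rng.normal(size=5), index=sims.columns)
        cfg = AbcConfig(retain_fraction=0.1)
        kept, _ = abc_reject(obs, sims, cfg)
        # brute force: standardize and sort all distances
        mat = sims.to_numpy()
        z = (mat - mat.mean(0)) / mat.std(0)
        zo = (obs.to_numpy() - mat.mean(0)) / mat.std(0)
        d = np.sqrt(((z - zo) ** 2).sum(1))
        expected = np.argsort(d, kind="stable")[:20]
        assert np.array_equal(np.sort(kept), np.sort(expected))

    def test_zero_variance_stat_dropped(self, caplog):
        rng = np.random.default_rng(9)
        sims = pd.DataFrame({"a": rng.normal(size=300), "const": 1.0})
        obs = pd.Series({"a": 0.0, "const": 1.0})
        kept, _ = abc_reject(obs, sims, AbcConfig(retain_fraction=0.1))
        assert len(kept) == 30


class TestRegressionAdjust:
    def _priors(self):
        return {"theta": ("linear", -100.0, 100.0)}

    def test_centroid_no_shift(self):
        rng = np.random.default_rng(10)
        stats_df = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        params = pd.DataFrame({"theta": rng.normal(size=400)})
        obs = stats_df.mean()
        adj = regression_adjust(params, stats_df, obs, self._priors())
        assert adj["theta"].mean() == pytest.approx(params["theta"].mean(), abs=1e-9)

    def test_independent_params_unchanged_distribution(self):
        rng = np.random.default_rng(11)
        stats_df = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        params = pd.DataFrame({"theta": rng.normal(size=500)})
        obs = pd.Series({"a": 0.5, "b": -0.5})
        adj = regression_adjust(params, stats_df, obs, self._priors())
        ks = stats.ks_2samp(adj["theta"], params["theta"])
        assert ks.pvalue > 0.01

    def test_linear_truth_recovered(self):
        rng = np.random.default_rng(12)
        s = rng.normal(size=600)
        stats_df = pd.DataFrame({"s": s})
        params = pd.DataFrame({"theta": 2.0 * s + rng.normal(scale=0.05, size=600)})
        obs = pd.Series({"s": 1.3})
        adj = regression_adjust(params, stats_df, obs, self._priors())
        assert adj["theta"].mean() == pytest.approx(2.6, rel=0.05)

    def test_log_scale_adjusted_and_clipped(self):
        rng = np.random.default_rng(13)
        s = rng.normal(size=500)
        params = pd.DataFrame({"ne": 10 ** (2 + 0.5 * s)})
        stats_df = pd.DataFrame({"s": s})
        obs = pd.Series({"s": 10.0})  # far outside -> big shift, then clipped
        priors = {"ne": ("log10", 100.0, 5000.0)}
        adj = regression_adjust(params, stats_df, obs, priors)
        assert adj["ne"].max() <= 5000.0
        assert adj["ne"].min() >= 100.0


class TestMarginalDensity:
    def test_far_observed_near_zero(self):
        rng = np.random.default_rng(14)
        retained = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        near = marginal_density(retained, pd.Series({"a": 0.0, "b": 0.0}))
        far = marginal_density(retained, pd.Series({"a": 50.0, "b": 50.0}))
        assert far < near * 1e-6

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(15)
        retained = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        obs = pd.Series({"a": 0.3, "b": -0.1})
        scaled = retained.copy()
        scaled["a"] = scaled["a"] * 1000
        obs2 = obs.copy()
        obs2["a"] = obs2["a"] * 1000
        assert marginal_density(retained, obs) == pytest.approx(
            marginal_density(scaled, obs2), rel=1e-9
        )

    def test_1d_standard_normal_oracle(self):
        rng = np.random.default_rng(16)
        retained = pd.DataFrame({"x": rng.normal(size=5000)})
        md = marginal_density(retained, pd.Series({"x": 0.0}))
        # analytic density at the peak; KDE is slightly biased downward
        assert md == pytest.approx(stats.norm.pdf(0.0), rel=0.06)


class TestPosteriorPvalue:
    def test_densest_point_high(self):
        rng = np.random.default_rng(17)
        retained = pd.DataFrame({"x": rng.normal(size=400)})
        assert posterior_pvalue(retained, pd.Series({"x": 0.0})) > 0.8

    def test_far_point_zero(self):
        rng = np.random.default_rng(18)
        retained = pd.DataFrame({"x": rng.normal(size=400)})
        assert posterior_pvalue(retained, pd.Series({"x": 40.0})) == 0.0

    def test_matches_exhaustive_density_sort(self):
        rng = np.random.default_rng(19)
        retained = pd.DataFrame({"x": rng.uniform(size=300)})
        obs = pd.Series({"x": 0.31})
        p = posterior_pvalue(retained, obs)
        # brute force with the same KDE definition
        x = retained["x"].to_numpy()
        z = (x - x.mean()) / x.std()
        zo = (0.31 - x.mean()) / x.std()
        h = z.std(ddof=1) * (4.0 / (3 * len(z))) ** 0.2
        dens = np.array([
            np.mean(np.exp(-0.5 * ((v - z) / h) ** 2) / (np.sqrt(2 * np.pi) * h))
            for v in z
        ])
        d_obs = np.mean(np.exp(-0.5 * ((zo - z) / h) ** 2) / (np.sqrt(2 * np.pi) * h))
        assert p == pytest.approx(np.mean(dens <= d_obs), abs=1e-9)


class TestBayesFactorAndComparison:
    def test_table_values(self):
        assert round(bayes_factor(5627.8, 308.1), 2) == 18.27
        assert round(bayes_factor(5627.8, 466.5), 2) == 12.06

    def test_equal_mds(self):
        assert bayes_factor(3.3, 3.3) == pytest.approx(1.0)

    def test_zero_denominator_inf(self):
        assert np.isinf(bayes_factor(1.0, 0.0))

    def test_matrix_consistency(self):
        res = {f"s{i}": (md, 0.5) for i, md in enumerate([10.0, 25.0, 2.0, 7.0])}
        comp = compare_scenarios(res)
        bf = comp.bf_matrix
        for i in bf.index:
            for j in bf.columns:
                for k in bf.columns:
                    assert bf.loc[i, j] * bf.loc[j, k] * bf.loc[k, i] == pytest.approx(1.0)
        assert np.allclose(np.diag(bf.values), 1.0)

    def test_single_scenario_best(self):
        comp = compare_scenarios({"only": (5.0, 0.4)})
        assert comp.best == "only" and comp.rejected == []

    def test_permutation_consistency(self):
        res = {"a": (10.0, 0.1), "b": (40.0, 0.2), "c": (5.0, 0.3)}
        comp1 = compare_scenarios(res)
        comp2 = compare_scenarios(dict(reversed(res.items())))
        assert comp1.best == comp2.best == "b"
        assert set(comp1.rejected) == set(comp2.rejected)
        assert comp1.bf_matrix.loc["a", "c"] == pytest.approx(
            comp2.bf_matrix.loc["a", "c"]
        )


class TestPosteriorSummaries:
    def test_point_mass(self):
        samples = pd.DataFrame({"theta": np.full(200, 3.7)})
        out = posterior_summaries(samples, {"theta": ("linear", 0, 10)})
        row = out.loc["theta"]
        assert row["mode"] == pytest.approx(3.7)
        assert row["q90_upper"] - row["q90_lower"] == pytest.approx(0.0)

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(20)
        samples = pd.DataFrame({"theta": rng.normal(size=20_000)})
        out = posterior_summaries(samples, {"theta": ("linear", -10, 10)})
        row = out.loc["theta"]
        assert row["mode"] == pytest.approx(0.0, abs=0.1)
        assert row["q90_lower"] == pytest.approx(-1.645, abs=0.06)
        assert row["q90_upper"] == pytest.approx(1.645, abs=0.06)

    def test_intervals_nested_mode_inside(self):
        rng = np.random.default_rng(21)
        samples = pd.DataFrame({
            "ne": 10 ** rng.uniform(2, 3.5, size=500),
            "t": rng.uniform(10, 90, size=500),
        })
        priors = {"ne": ("log10", 100, 5000), "t": ("linear", 5, 150)}
        out = posterior_summaries(samples, priors)
        for name, row in out.iterrows():
            assert row["q90_lower"] <= row["q50_lower"] <= row["q50_upper"] <= row["q90_upper"]
            assert row["q90_lower"] <= row["mode"] <= row["q90_upper"]

    def test_requires_100_samples(self):
        with pytest.raises(ValueError):
            posterior_summaries(pd.DataFrame({"x": np.arange(50)}), {})
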