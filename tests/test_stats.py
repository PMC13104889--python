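"""Preprocessing, feature clustering, effect sizes and enrichment tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lncuncert import stats
from lncuncert.simulate import SimulationConfig, generate_features


def brute_vda(x, y):
    """Pair-enumeration oracle for the Vargha-Delaney A statistic."""
    wins = sum(1.0 for a, b in itertools.product(x, y) if a > b)
    ties = sum(1.0 for a, b in itertools.product(x, y) if a == b)
    return (wins + 0.5 * ties) / (len(x) * len(y))


class TestPreprocess:
    def test_constant_and_allmissing_dropped(self):
        df = pd.DataFrame({"c": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0],
                           "m": [np.nan] * 3})
        kinds = {"c": "continuous", "x": "continuous", "m": "continuous"}
        cont, ind, report = stats.preprocess(df, kinds)
        assert list(cont.columns) == ["x"]
        assert report == {"c": "constant", "m": "all missing"}

    def test_three_level_categorical_gets_three_indicators(self):
        df = pd.DataFrame({"cat": ["a", "b", "c", "a"]})
        _, ind, _ = stats.preprocess(df, {"cat": "categorical"})
        assert ind.shape[1] == 3
        assert (ind.sum(axis=1) == 1).all()

    def test_no_categoricals_gives_empty_indicator_block(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        _, ind, _ = stats.preprocess(df, {"x": "continuous"})
        assert ind.shape == (3, 0)


class TestClustering:
    def test_recovers_planted_blocks(self, rng):
        # two internally correlated blocks of 5 plus 3 independent features
        n = 400
        g1, g2 = rng.normal(size=n), rng.normal(size=n)
        cols = {f"a{i}": g1 + rng.normal(0, 0.2, n) for i in range(5)}
        cols |= {f"b{i}": g2 + rng.normal(0, 0.2, n) for i in range(5)}
        cols |= {f"n{i}": rng.normal(size=n) for i in range(3)}
        clust = stats.cluster_features(pd.DataFrame(cols))
        ca = {clust.cluster_of[f"a{i}"] for i in range(5)}
        cb = {clust.cluster_of[f"b{i}"] for i in range(5)}
        assert len(ca) == 1 and len(cb) == 1 and ca != cb
        noise_clusters = {clust.cluster_of[f"n{i}"] for i in range(3)}
        assert not (noise_clusters & (ca | cb))

    def test_duplicated_feature_always_coclustered(self, rng):
        n = 200
        x = rng.normal(size=(n, 4))
        df = pd.DataFrame(x, columns=list("wxyz"))
        df["x_copy"] = df["x"]
        clust = stats.cluster_features(df)
        assert clust.cluster_of["x"] == clust.cluster_of["x_copy"]

    def test_uncorrelated_features_have_no_cluster_structure(self, rng):
        # without correlation structure the best achievable silhouette is
        # near zero, unlike planted blocks where it is high
        df = pd.DataFrame(rng.normal(size=(500, 8)),
                          columns=[f"f{i}" for i in range(8)])
        clust = stats.cluster_features(df)
        assert np.nanmax(clust.silhouettes) < 0.25
        n = 500
        g1, g2 = rng.normal(size=n), rng.normal(size=n)
        blocks = {f"a{i}": g1 + rng.normal(0, 0.2, n) for i in range(4)}
        blocks |= {f"b{i}": g2 + rng.normal(0, 0.2, n) for i in range(4)}
        structured = stats.cluster_features(pd.DataFrame(blocks))
        assert np.nanmax(structured.silhouettes) > 0.5

    def test_fewer_than_three_features_single_cluster(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [3.0, 2, 1]})
        clust = stats.cluster_features(df)
        assert clust.n_clusters == 1


class TestRepresentatives:
    def _clustering(self):
        df = pd.DataFrame({
            "a": [1, 2, 3, 4, 5.0], "a2": [1.1, 2, 3, 4, 5.1],
            "b": [5, 3, 1, 2, 4.0]})
        df["a3"] = df["a"] + 0.01
        return stats.cluster_features(df)

    def test_max_effect_picks_largest_magnitude(self):
        clust = self._clustering()
        effects = {"a": 0.1, "a2": -0.4, "a3": 0.2, "b": 0.05}
        reps = stats.select_representatives(clust, "max_effect",
                                            effect_fn=effects.get)
        assert "a2" in reps and "b" in reps

    def test_forced_feature_wins_its_cluster(self):
        clust = self._clustering()
        effects = {"a": 0.1, "a2": -0.4, "a3": 0.2, "b": 0.05}
        reps = stats.select_representatives(clust, "max_effect",
                                            effect_fn=effects.get,
                                            forced=["a"])
        assert "a" in reps and "a2" not in reps

    def test_random_mode_deterministic_given_seed(self):
        clust = self._clustering()
        r1 = stats.select_representatives(clust, "random", seed=3)
        r2 = stats.select_representatives(clust, "random", seed=3)
        assert r1 == r2


class TestVDA:
    def test_complete_separation(self):
        _, _, cvda = stats.mannwhitney_vda([4, 5, 6], [1, 2, 3])
        assert cvda == pytest.approx(0.5)

    def test_identical_samples_no_effect(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert stats.vda(x, x) - 0.5 == pytest.approx(0.0)

    def test_four_pair_enumeration(self):
        _, _, cvda = stats.mannwhitney_vda([1, 2], [1, 3])
        assert cvda == pytest.approx(-0.125)

    def test_pair_count_conservation(self, rng):
        for _ in range(200):
            x = rng.integers(0, 10, size=rng.integers(1, 12)).astype(float)
            y = rng.integers(0, 10, size=rng.integers(1, 12)).astype(float)
            assert stats.vda(x, y) + stats.vda(y, x) == pytest.approx(1.0)

    def test_rank_formula_matches_pair_enumeration(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 40))
            y = np.round(rng.normal(size=rng.integers(2, 40)), 1)
            assert stats.vda(x, y) == pytest.approx(brute_vda(x, y))


class TestChiSquared:
    def test_hand_computed_2x2(self):
        chi2, p, v, odds = stats.chisq_cramers([[30, 10], [10, 30]])
        assert chi2 == pytest.approx(20.0)
        assert v == pytest.approx(0.5)
        assert odds == pytest.approx(9.0)

    def test_perfect_association(self):
        _, _, v, _ = stats.chisq_cramers([[20, 0], [0, 20]])
        assert v == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        _, _, v, _ = stats.chisq_cramers([[10, 20], [20, 40]])
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        _, _, _, odds = stats.chisq_cramers([[20, 0], [10, 10]])
        assert odds == pytest.approx(20.5 * 10.5 / (0.5 * 10.5))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            stats.chisq_cramers([[0, 0], [5, 5]])


class TestBH:
    def test_stepup_by_hand(self):
        adj = stats.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04] * 4)

    def test_single_p_unchanged(self):
        assert stats.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_monotone_and_at_least_raw(self, rng):
        p = rng.random(50)
        adj = stats.bh_adjust(p)
        assert (adj >= p - 1e-15).all() and adj.max() <= 1.0
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.5])


class TestEnrichment:
    def test_complete_separation_is_significant(self, rng):
        n = 60
        df = pd.DataFrame({"f": np.r_[rng.uniform(10, 11, n),
                                      rng.uniform(0, 1, n)]})
        comp = {"a_vs_b": (df.index[:n], df.index[n:])}
        res = stats.run_enrichment(df, {"f": "continuous"}, comp)
        row = res.iloc[0]
        assert row["significant"] and row["effect"] == pytest.approx(0.5)
        assert row["direction"] == "a"

    def test_planted_effect_recovered_within_tolerance(self, rng):
        # quantile shift delta = sqrt(2)*Phi^-1(0.8) plants cVDA ~ 0.3
        from scipy.stats import norm
        delta = np.sqrt(2) * norm.ppf(0.8)
        n = 2000
        df = pd.DataFrame({"f": np.r_[rng.normal(delta, 1, n),
                                      rng.normal(0, 1, n)]})
        comp = {"shift": (df.index[:n], df.index[n:])}
        res = stats.run_enrichment(df, {"f": "continuous"}, comp)
        assert res.iloc[0]["effect"] == pytest.approx(0.3, abs=0.05)

    def test_small_group_skipped(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        res = stats.run_enrichment(df, {"f": "continuous"},
                                   {"bad": (df.index[:1], df.index[1:])})
        assert "bad" in res.attrs["skipped"]

    def test_null_features_rarely_flagged(self):
        # no planted shift: block_class_shift all zero -> BH at 1% controls
        # the flagged fraction across seeded replicates
        flagged = total = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_coding=150, n_lnc=150, n_feature_blocks=2,
                block_sizes=(1, 1), block_class_shift=(0.0, 0.0),
                n_independent=10, n_categorical=2,
                categorical_rates=((0.4, 0.4), (0.6, 0.6)), seed=seed)
            feats, kinds = generate_features(cfg)
            labels = cfg.labels()
            comp = {"c_vs_l": (labels.index[labels == "coding"],
                               labels.index[labels == "lncRNA"])}
            res = stats.run_enrichment(feats, kinds, comp)
            flagged += int(res["significant"].sum())
            total += len(res)
        assert flagged / total <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / total)
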