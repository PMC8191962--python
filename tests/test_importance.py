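"""Importance methods: OOB forest, rankers, ReliefF, CWF, graph, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strainrank.importance import (
    ImportanceRanking,
    RFConfig,
    correlation_graph,
    cwf_combine,
    edge_thickness,
    oob_importance,
    rank_by_kbest,
    rank_by_relief,
    rank_by_rfe,
    rank_by_target_correlation,
    rank_by_welch_t,
    ranking_overlap,
    relief_weights,
    view_census,
)
from strainrank.published import PUBLISHED_CWF_TOP20, PUBLISHED_OOB_TOP20


def _toy(n=120, p=20, effect=2.0, seed=0):
    """Gaussian noise matrix with one shifted column ('f0')."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += effect * y
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y


class TestRankingContainer:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            ImportanceRanking("m", [("a", 1.0), ("a", 0.5)])

    @pytest.mark.parametrize(
        "ranker",
        [rank_by_target_correlation, rank_by_welch_t, rank_by_kbest, rank_by_rfe, rank_by_relief],
    )
    def test_rankers_return_permutation_of_features(self, ranker):
        X, y = _toy(n=40, p=8)
        rk = ranker(X, y)
        assert sorted(rk.features) == sorted(X.columns)


class TestOOBImportance:
    def test_normalized_max_is_one(self):
        X, y = _toy()
        rk = oob_importance(X, y, RFConfig(n_trees=150, max_features_per_tree=5, seed=0))
        assert rk.normalized
        assert max(s for _, s in rk.entries) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        X, y = _toy()
        cfg = RFConfig(n_trees=80, max_features_per_tree=5, seed=3)
        assert oob_importance(X, y, cfg).entries == oob_importance(X, y, cfg).entries

    def test_recovers_single_strong_feature(self):
        """A feature with Welch |t| > 8 among 157 noise features ranks first."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 130
            y = np.repeat([0, 1], [47, 83])
            X = rng.normal(size=(n, 158))
            X[:, 42] += 2.0 * y  # d=2 -> t ~ 11 at this n
            rk = oob_importance(X, y, RFConfig(seed=seed))
            hits += rk.features[0] == "f42"
        assert hits >= 9

    def test_permuted_labels_give_no_stable_winner(self):
        """After label permutation the formerly strong feature loses its rank."""
        top1 = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X, y = _toy(n=120, p=40, effect=2.0, seed=seed)
            y_perm = rng.permutation(y)
            rk = oob_importance(X, y_perm, RFConfig(n_trees=200, seed=seed))
            top1 += rk.features[0] == "f0"
        assert top1 <= 1

    def test_single_class_rejected(self):
        X, _ = _toy(n=20)
        with pytest.raises(ValueError):
            oob_importance(X, np.zeros(20), RFConfig(n_trees=10))

    def test_missing_values_rejected(self):
        X, y = _toy(n=20, p=4)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            oob_importance(X, y, RFConfig(n_trees=10, max_features_per_tree=2))


class TestCorrelationGraph:
    def test_affine_copy_thickness_five(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": 3.0 * a - 1.0})
        g = correlation_graph(X)
        assert g.number_of_edges() == 1
        assert g.edges["a", "b"]["thickness"] == pytest.approx(5.0)
        assert g.edges["a", "b"]["abs_r"] == pytest.approx(1.0)

    def test_edge_absent_at_exactly_half(self):
        """|r| = 0.5 exactly is below the strict threshold: no edge drawn."""
        rng = np.random.default_rng(1)
        a = rng.normal(size=400)
        z = rng.normal(size=400)
        # orthogonalize then mix for an exact sample correlation of 0.5
        a = (a - a.mean()) / a.std()
        z = z - z.mean() - a * (z @ a) / (a @ a) * 1.0
        z = z / z.std()
        b = 0.5 * a + np.sqrt(1 - 0.25) * z
        X = pd.DataFrame({"a": a, "b": b})
        r = abs(np.corrcoef(a, b)[0, 1])
        assert r == pytest.approx(0.5, abs=1e-12)
        g = correlation_graph(X)
        assert g.number_of_edges() == 0

    def test_thickness_formula(self):
        assert edge_thickness(1.0) == 5.0
        assert edge_thickness(0.75) == pytest.approx(2.5)
        assert edge_thickness(0.5) == pytest.approx(0.0)

    def test_zero_variance_feature_excluded_with_warning(self):
        X = pd.DataFrame({"a": np.arange(10.0), "c": np.full(10, 2.0)})
        with pytest.warns(UserWarning, match="zero-variance"):
            g = correlation_graph(X)
        assert "c" not in g.nodes

    def test_all_edges_above_threshold_thickness_in_range(self, cohort_features):
        feats, _ = cohort_features
        X = feats.drop(columns=["patient_id", "response"]).dropna(axis=1)
        g = correlation_graph(X, features=list(X.columns[:40]))
        for _, _, d in g.edges(data=True):
            assert d["abs_r"] > 0.5
            assert 0.0 < d["thickness"] <= 5.0


class TestUnivariateRankers:
    def test_label_copy_has_perfect_correlation(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        X = pd.DataFrame({"label_copy": y.astype(float), "noise": rng.normal(size=60)})
        rk = rank_by_target_correlation(X, y)
        assert rk.features[0] == "label_copy"
        assert rk.entries[0][1] == pytest.approx(1.0)

    def test_noise_correlation_small_at_large_n(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0, 1], 500)
        X = pd.DataFrame({"noise": rng.normal(size=1000)})
        assert rank_by_target_correlation(X, y).entries[0][1] < 0.1

    def test_constant_feature_scores_zero_and_last(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 20)
        X = pd.DataFrame({"x": rng.normal(size=40) + y, "const": np.full(40, 3.3)})
        for ranker in (rank_by_target_correlation, rank_by_welch_t, rank_by_kbest):
            rk = ranker(X, y)
            assert rk.features[-1] == "const"
            assert rk.entries[-1][1] == 0.0

    def test_welch_t_strong_shift(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 50)
        X = pd.DataFrame({"x": rng.normal(size=100) + 3.0 * y})
        assert rank_by_welch_t(X, y).entries[0][1] > 8

    def test_welch_t_on_published_cohort_age_row(self):
        """Age 67.1±10.5 (n=83) vs 65.6±12.3 (n=47): not significant (p>0.05)."""
        res = stats.ttest_ind_from_stats(67.1, 10.5, 83, 65.6, 12.3, 47, equal_var=False)
        assert res.pvalue > 0.05

    def test_kbest_orders_like_squared_pooled_t(self):
        """For two classes ANOVA F equals the squared pooled-variance t."""
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 40)
        X = pd.DataFrame(rng.normal(size=(80, 10)), columns=[f"f{i}" for i in range(10)])
        X.iloc[:, 3] += 0.8 * y
        f_rank = rank_by_kbest(X, y)
        t2 = {}
        for c in X.columns:
            t, _ = stats.ttest_ind(X[c][y == 1], X[c][y == 0], equal_var=True)
            t2[c] = t * t
        expected = sorted(X.columns, key=lambda c: (-t2[c], c))
        assert f_rank.features == expected
        assert f_rank.features[0] == "f3"


class TestRFE:
    def test_recovers_separating_feature(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            X = pd.DataFrame(rng.normal(size=(60, 20)), columns=[f"f{i:02d}" for i in range(20)])
            X["f07"] += 4.0 * y  # near-perfect separator
            hits += rank_by_rfe(X, y).features[0] == "f07"
        assert hits >= 19

    def test_duplicated_feature_tie_break(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 20)
        base = rng.normal(size=40) + y
        X = pd.DataFrame({"dup_a": base, "dup_b": base, "noise": rng.normal(size=40)})
        rk = rank_by_rfe(X, y)
        assert sorted(rk.features) == ["dup_a", "dup_b", "noise"]
        # deterministic under repetition
        assert rk.entries == rank_by_rfe(X, y).entries

    def test_single_feature(self):
        y = np.repeat([0, 1], 5)
        X = pd.DataFrame({"only": np.arange(10.0)})
        rk = rank_by_rfe(X, y)
        assert rk.features == ["only"]


class TestRelief:
    def test_two_sample_hand_trace(self):
        """x=0 (class A) vs x=1 (class B), k=1: each sample's nearest miss differs
        by the full scaled range and there are no hits, so the weight is +1."""
        X = pd.DataFrame({"x": [0.0, 1.0]})
        y = np.array([0, 1])
        w = relief_weights(X, y, k_neighbors=1)
        assert w[0] == pytest.approx(1.0)

    def test_irrelevant_feature_weight_near_zero(self):
        rng = np.random.default_rng(11)
        y = np.repeat([0, 1], 250)
        X = pd.DataFrame({"noise": rng.normal(size=500)})
        w = relief_weights(X, y, k_neighbors=10)
        assert abs(w[0]) < 0.05

    def test_xor_interaction_detected(self):
        """ReliefF ranks an XOR feature pair above marginally-irrelevant noise."""
        rng = np.random.default_rng(2)
        n = 400
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        y = a ^ b
        X = pd.DataFrame(
            {
                "xor_a": a + rng.normal(scale=0.05, size=n),
                "xor_b": b + rng.normal(scale=0.05, size=n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        rk = rank_by_relief(X, y, k_neighbors=10)
        assert set(rk.features[:2]) == {"xor_a", "xor_b"}

    def test_matches_brute_force_neighbor_scan(self):
        """Vectorized ReliefF equals a naive per-sample neighbor scan."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 31))
            p = int(rng.integers(1, 6))
            k = int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                y[0] = 1 - y[0]
            expected = _relief_brute_force(X, y, k)
            got = relief_weights(pd.DataFrame(X), y, k_neighbors=k)
            np.testing.assert_allclose(got, expected, atol=1e-12)


def _relief_brute_force(X, y, k):
    """Literal ReliefF: per-sample nearest hits/misses by explicit sorting."""
    X = np.asarray(X, dtype=float)
    rng_range = X.max(axis=0) - X.min(axis=0)
    Z = (X - X.min(axis=0)) / np.where(rng_range > 0, rng_range, 1.0)
    n, p = Z.shape
    w = np.zeros(p)
    for i in range(n):
        dists = [(np.sqrt(((Z[i] - Z[j]) ** 2).sum()), j) for j in range(n) if j != i]
        hits = sorted((d, j) for d, j in dists if y[j] == y[i])[:k]
        misses = sorted((d, j) for d, j in dists if y[j] != y[i])[:k]
        if hits:
            w -= np.mean([np.abs(Z[i] - Z[j]) for _, j in hits], axis=0)
        if misses:
            w += np.mean([np.abs(Z[i] - Z[j]) for _, j in misses], axis=0)
    return w / n


class TestCWF:
    def _ranking(self, names, method="m"):
        return ImportanceRanking(method, [(n, float(len(names) - i)) for i, n in enumerate(names)])

    def test_hand_computed_mean_rank(self):
        """Feature at ranks 1, 3, 5 in three methods and absent in two: mean 3.0."""
        universe = [f"x{i:02d}" for i in range(30)]
        lists = []
        placements = [0, 2, 4]  # 0-based ranks 1, 3, 5
        for m in range(3):
            others = [u for u in universe if u != "target"]
            lst = others[:20]
            lst.insert(placements[m], "target")
            lists.append(self._ranking(lst[:20] + [u for u in universe if u not in lst[:20]], f"m{m}"))
        for m in range(3, 5):
            lists.append(self._ranking([u for u in universe if u != "target"] + ["target"], f"m{m}"))
        combined = cwf_combine(lists)
        scores = dict(combined.entries)
        assert scores["target"] == pytest.approx(3.0)

    def test_two_method_feature_excluded(self):
        universe = [f"x{i:02d}" for i in range(25)]
        in_two = self._ranking(["special"] + universe[:24])
        without = self._ranking(universe + ["special"])
        combined = cwf_combine([in_two, in_two, without, without, without])
        assert "special" not in combined.features

    def test_identical_rankings_fixed_point(self):
        universe = [f"x{i:02d}" for i in range(40)]
        rk = self._ranking(universe)
        combined = cwf_combine([rk] * 5)
        assert combined.features == universe[:20]

    def test_requires_five_rankings(self):
        rk = self._ranking(["a", "b"])
        with pytest.raises(ValueError):
            cwf_combine([rk] * 4)

    def test_matches_brute_force_on_random_quintuples(self):
        rng = np.random.default_rng(0)
        universe = [f"x{i:02d}" for i in range(30)]
        for _ in range(100):
            lists = []
            for m in range(5):
                perm = list(rng.permutation(universe))
                lists.append(self._ranking(perm, f"m{m}"))
            combined = cwf_combine(lists)
            expected = _cwf_brute_force([rk.features for rk in lists])
            assert [(n, pytest.approx(s)) for n, s in combined.entries] == expected


def _cwf_brute_force(feature_lists, top_k=20, min_methods=3):
    """Naive restatement of the combination rule."""
    ranks = {}
    for lst in feature_lists:
        for pos, name in enumerate(lst[:top_k], start=1):
            ranks.setdefault(name, []).append(pos)
    eligible = {n: np.mean(rs) for n, rs in ranks.items() if len(rs) >= min_methods}
    ordered = sorted(eligible.items(), key=lambda kv: (kv[1], kv[0]))
    return [(n, pytest.approx(s)) for n, s in ordered]


class TestSummaries:
    def test_view_census_of_published_oob_list(self):
        census = view_census(list(PUBLISHED_OOB_TOP20))
        assert census == {"4ch": 12, "3ch": 3, "2ch": 5, "none": 0}

    def test_view_census_empty_and_clinical(self):
        assert view_census([]) == {"4ch": 0, "3ch": 0, "2ch": 0, "none": 0}
        assert view_census(["QRS", "LVEF"])["none"] == 2

    def test_overlap_of_published_lists(self):
        assert ranking_overlap(list(PUBLISHED_OOB_TOP20), list(PUBLISHED_CWF_TOP20)) == 10

    def test_overlap_identical_and_disjoint(self):
        a = [f"a{i}" for i in range(20)]
        b = [f"b{i}" for i in range(20)]
        assert ranking_overlap(a, a) == 20
        assert ranking_overlap(a, b) == 0
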