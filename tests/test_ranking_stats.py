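import math

import numpy as np
import pytest

from pylseeker.ranking_stats import (
    NullDistribution,
    final_ranking,
    mean_rank_closed_form,
    mean_rank_pvalue,
    optimize_weights,
    rank_clusters,
    sample_mean_rank_null,
    select_significant_features,
)


class TestNull:
    @pytest.mark.parametrize("N,n", [(958, 6), (100, 3), (50, 10)])
    def test_matches_finite_population_closed_form(self, N, n):
        null = sample_mean_rank_null(N, n, reps=100_000, seed=0)
        mu, sigma = mean_rank_closed_form(N, n)
        assert abs(null.mu - mu) / mu < 0.02
        assert abs(null.sigma - sigma) / sigma < 0.02

    def test_degenerate_single_rank(self):
        null = sample_mean_rank_null(1, 1, reps=10, seed=0)
        assert null.mu == 1.0 and null.sigma == 0.0 and null.degenerate

    def test_rejects_n_greater_than_N(self):
        with pytest.raises(ValueError):
            sample_mean_rank_null(5, 6)

    def test_seeded_reproducibility(self):
        a = sample_mean_rank_null(100, 4, reps=2000, seed=3)
        b = sample_mean_rank_null(100, 4, reps=2000, seed=3)
        assert a.mu == b.mu and a.sigma == b.sigma


@pytest.fixture(scope="module")
def null958():
    return sample_mean_rank_null(958, 6, reps=100_000, seed=1)


class TestPvalues:
    @pytest.mark.parametrize(
        "ranks,published,rel_tol",
        [
            ((1, 3, 2, 84, 508, 85), 0.0006, 0.20),
            ((22, 26, 38, 31, 80, 76), 0.00006, 0.25),
            ((6, 7, 13, 46, 32, 41), 0.000027, 0.25),
            ((8, 9, 6, 10, 305, 498), 0.0013, 0.20),
            ((895, 344, 858, 196, 147, 840), 0.72, 0.02),
            ((32, 222, 87, 639, 890, 243), 0.13, 0.05),
            ((793, 385, 596, 252, 99, 762), 0.51, 0.02),
            ((4, 5, 10, 16, 18, 19), 0.000017, 0.25),
        ],
    )
    def test_published_cluster_ranks_reproduce_pvalues(self, null958, ranks, published, rel_tol):
        p = mean_rank_pvalue(ranks, null958)
        assert math.isclose(p, published, rel_tol=rel_tol)

    def test_mean_at_mu_gives_half(self):
        null = NullDistribution(100, 2, 10, mu=50.0, sigma=10.0)
        assert math.isclose(mean_rank_pvalue([40, 60], null), 0.5)

    def test_monotone_in_mean_rank(self):
        null = NullDistribution(100, 1, 10, mu=50.0, sigma=10.0)
        ps = [mean_rank_pvalue([r], null) for r in (10, 20, 30, 40, 50)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_input_validation(self):
        null = NullDistribution(100, 1, 10, mu=50.0, sigma=10.0)
        with pytest.raises(ValueError):
            mean_rank_pvalue([], null)
        with pytest.raises(ValueError):
            mean_rank_pvalue([0], null)


class TestRanking:
    def test_high_is_best(self):
        ranks = rank_clusters({"a": 5.0, "b": 9.0, "c": 1.0})
        assert ranks == {"b": 1, "a": 2, "c": 3}

    def test_ties_broken_by_cluster_id(self):
        ranks = rank_clusters({"b": 1.0, "a": 1.0, "c": 1.0})
        assert ranks == {"a": 1, "b": 2, "c": 3}

    def test_low_direction(self):
        ranks = rank_clusters({"a": 5.0, "b": 9.0}, direction="low")
        assert ranks == {"a": 1, "b": 2}

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(0)
        values = {f"c{i}": float(v) for i, v in enumerate(rng.integers(0, 5, size=40))}
        ranks = rank_clusters(values)
        assert sorted(ranks.values()) == list(range(1, 41))


class TestSelection:
    def test_published_table_selection(self):
        pvalues = {
            "f_organisms": 0.0006, "f_diversity": 0.13, "f_structure": 0.72,
            "f_coding": 0.00006, "f_upstream": 0.000027, "f_downstream": 0.064,
            "f_syn_codons": 0.51, "f_size": 0.0013,
            "c_coding_upstream": 0.000017, "c_structure_diversity_syn": 0.13,
        }
        selected = select_significant_features(pvalues)
        assert set(selected) == {
            "f_organisms", "f_coding", "f_upstream", "f_size", "c_coding_upstream"
        }

    def test_alpha_extremes(self):
        pvalues = {"a": 1.0, "b": 0.5}
        assert select_significant_features(pvalues, alpha=1.0) == ["a", "b"]
        assert select_significant_features({"a": 1.0}, alpha=0.05) == []


def random_instance(rng, n_clusters=958, n_pos=6, k=4):
    """Clusters with uniform features; positives boosted on the first
    features to mimic the published rank profile (good on some features,
    mediocre on others)."""
    features = {}
    for i in range(n_clusters):
        features[f"c{i:04d}"] = {f"f{j}": float(rng.uniform(0, 0.8)) for j in range(k)}
    positives = [f"c{i:04d}" for i in range(n_pos)]
    for idx, p in enumerate(positives):
        for j in range(k):
            if j < 2 or idx % 2 == 0:
                features[p][f"f{j}"] = float(rng.uniform(0.75, 1.0))
    return features, positives


class TestWeightOptimization:
    def test_separable_case_puts_positives_on_top(self):
        rng = np.random.default_rng(0)
        features = {f"c{i}": {"good": float(rng.uniform(0, 0.5)),
                              "noise": float(rng.uniform(0, 1))} for i in range(50)}
        positives = ["c0", "c1", "c2"]
        for p in positives:
            features[p]["good"] = float(rng.uniform(0.9, 1.0))
        model = optimize_weights(features, ["good", "noise"], positives, seed=0)
        assert model.objective == 1 + 2 + 3
        assert model.weights["good"] > model.weights["noise"]

    def test_improves_on_equal_weights(self):
        rng = np.random.default_rng(1)
        features, positives = random_instance(rng)
        selected = sorted(next(iter(features.values())))
        model = optimize_weights(features, selected, positives, seed=0)
        equal = np.ones(len(selected)) / len(selected)
        scores = {
            cid: float(np.dot(equal, [features[cid][f] for f in selected]))
            for cid in features
        }
        equal_obj = sum(rank_clusters(scores)[p] for p in positives)
        assert model.objective <= equal_obj

    def test_never_worse_than_best_single_feature(self):
        rng = np.random.default_rng(2)
        features, positives = random_instance(rng, n_clusters=200, n_pos=4)
        selected = sorted(next(iter(features.values())))
        model = optimize_weights(features, selected, positives, seed=0)
        for feat in selected:
            ranks = rank_clusters({cid: features[cid][feat] for cid in features})
            assert model.objective <= sum(ranks[p] for p in positives)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        features, positives = random_instance(rng, n_clusters=120, n_pos=4, k=3)
        order_a = ["f0", "f1", "f2"]
        order_b = ["f2", "f0", "f1"]
        ma = optimize_weights(features, order_a, positives, seed=0)
        mb = optimize_weights(features, order_b, positives, seed=0)
        for f in order_a:
            assert math.isclose(ma.weights[f], mb.weights[f], abs_tol=1e-8)

    def test_degenerate_features_rejected(self):
        features = {f"c{i}": {"f0": 0.5} for i in range(10)}
        with pytest.raises(ValueError):
            optimize_weights(features, ["f0"], ["c0"], seed=0)

    def test_requires_positives_and_features(self):
        features = {"a": {"f0": 0.1}, "b": {"f0": 0.9}}
        with pytest.raises(ValueError):
            optimize_weights(features, ["f0"], [], seed=0)
        with pytest.raises(ValueError):
            optimize_weights(features, [], ["a"], seed=0)

    def test_coordinate_search_mode(self):
        rng = np.random.default_rng(4)
        features, positives = random_instance(rng, n_clusters=60, n_pos=3, k=3)
        selected = ["f0", "f1", "f2"]
        model = optimize_weights(features, selected, positives, seed=0, method="coordinate")
        vertex_best = min(
            sum(rank_clusters({c: features[c][f] for c in features})[p] for p in positives)
            for f in selected
        )
        assert model.objective <= vertex_best


class TestFinalRanking:
    def test_single_feature_ranking_matches_feature_order(self):
        rng = np.random.default_rng(5)
        features = {f"c{i}": {"f0": float(rng.uniform()), "f1": 0.5} for i in range(20)}
        model = optimize_weights(features, ["f0"], ["c0"], seed=0)
        table = final_ranking(model, features)
        by_feature = rank_clusters({c: features[c]["f0"] for c in features})
        got = dict(zip(table.cluster_id, table["rank"]))
        assert got == by_feature

    def test_scale_invariance_of_ranking(self):
        features = {f"c{i}": {"f0": i / 10, "f1": (9 - i) / 10} for i in range(10)}
        m1 = optimize_weights(features, ["f0", "f1"], ["c9"], seed=0)
        t1 = final_ranking(m1, features)
        # doubling all weights rescales scores but not the order
        m1.weights = {k: 2 * v for k, v in m1.weights.items()}
        t2 = final_ranking(m1, features)
        assert list(t1.cluster_id) == list(t2.cluster_id)

    def test_positive_flagging(self):
        features = {"a": {"f0": 1.0}, "b": {"f0": 0.2}}
        model = optimize_weights(features, ["f0"], ["a"], seed=0)
        table = final_ranking(model, features)
        assert bool(table[table.cluster_id == "a"].is_positive.iloc[0])
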