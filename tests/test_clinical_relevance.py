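import numpy as np
import pandas as pd
import pytest

from dvpclust.clinical_relevance import (
    cluster_means_normalized,
    csm_table,
    csm_weighted_distance,
    kruskal_then_welch,
    quantile_distance,
)


class TestClusterMeans:
    def test_single_cluster_equals_dataset_normalized_mean(self, rng):
        table = pd.DataFrame({"age": rng.normal(50, 10, 100)})
        out = cluster_means_normalized(np.zeros(100, dtype=int), table)
        x = table["age"].to_numpy()
        expected = ((x - x.min()) / (x.max() - x.min())).mean()
        assert out.loc[0, "age"] == pytest.approx(expected)

    def test_values_in_unit_interval(self, rng):
        table = pd.DataFrame({"age": rng.normal(50, 10, 90), "BMI": rng.normal(25, 4, 90)})
        out = cluster_means_normalized(rng.integers(0, 3, 90), table)
        assert ((out >= 0) & (out <= 1)).all().all()

    def test_youngest_planted_class_has_lowest_age_mean(self, planted_dataset):
        _, clinical, labels = planted_dataset
        out = cluster_means_normalized(labels, clinical, variables=["age"])
        assert out["age"].idxmin() == 1  # class 1 = youngest subjects


class TestKruskalWelch:
    def test_identical_distributions_no_rejections(self, rng):
        table = pd.DataFrame({"age": np.tile(np.arange(50.0), 2)})
        labels = np.repeat([0, 1], 50)
        rep = kruskal_then_welch(labels, table)
        assert not rep.kruskal["significant"].any()
        assert rep.welch.empty

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_large_separation_rejected_by_both_tests(self, seed):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {"age": np.concatenate([rng.normal(40, 5, 100), rng.normal(60, 5, 100)])}
        )
        labels = np.repeat([0, 1], 100)
        rep = kruskal_then_welch(labels, table)
        assert rep.kruskal["significant"].all()
        assert rep.welch["significant"].all()

    def test_welch_only_for_significant_variables(self, rng):
        same = np.tile(np.arange(60.0), 2)
        table = pd.DataFrame(
            {"age": np.concatenate([rng.normal(40, 5, 60), rng.normal(60, 5, 60)]),
             "BMI": same}
        )
        rep = kruskal_then_welch(np.repeat([0, 1], 60), table)
        assert set(rep.welch["variable"]) <= set(
            rep.kruskal.loc[rep.kruskal["significant"], "variable"]
        )

    def test_degenerate_cluster_sizes_skip_with_warning(self, rng):
        table = pd.DataFrame({"age": rng.normal(50, 5, 5)})
        labels = np.array([0, 0, 0, 0, 1])  # cluster 1 has a single member
        with pytest.warns(UserWarning):
            rep = kruskal_then_welch(labels, table)
        assert rep.kruskal.empty


class TestQuantileDistance:
    def test_identical_samples_zero(self, rng):
        x = rng.random(50)
        assert quantile_distance(x, x.copy()) == 0.0

    @pytest.mark.parametrize("kind", ["mean_abs", "rms"])
    def test_point_masses_unit_gap(self, kind):
        assert quantile_distance(np.zeros(20), np.ones(20), kind=kind) == pytest.approx(1.0)

    def test_pure_shift_measured_exactly(self, rng):
        x = rng.normal(0, 1, 200)
        c = 3.7
        assert quantile_distance(x, x + c) == pytest.approx(c, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_distance(np.array([]), np.ones(3))


class TestCSM:
    def test_identical_cluster_distributions_give_zero(self):
        values = np.tile(np.arange(30.0), 3)
        labels = np.repeat([0, 1, 2], 30)
        assert csm_weighted_distance(labels, values).d == 0.0

    def test_two_point_mass_clusters_worked_example(self):
        values = np.concatenate([np.zeros(10), np.ones(10)])
        labels = np.repeat([0, 1], 10)
        assert csm_weighted_distance(labels, values).d == pytest.approx(0.25)

    def test_positive_homogeneity_with_identity_normalization(self, rng):
        values = rng.normal(0, 1, 120)
        labels = rng.integers(0, 3, 120)
        d1 = csm_weighted_distance(labels, values, normalization="identity").d
        d2 = csm_weighted_distance(labels, 4.0 * values, normalization="identity").d
        assert d2 == pytest.approx(4.0 * d1)

    def test_weights_sum_to_one_and_size_doubling_invariance(self, rng):
        values = rng.normal(0, 1, 60)
        labels = rng.integers(0, 3, 60)
        rep = csm_weighted_distance(labels, values)
        assert rep.weights.sum() == pytest.approx(1.0)
        rep2 = csm_weighted_distance(np.tile(labels, 2), np.tile(values, 2))
        np.testing.assert_allclose(rep2.weights, rep.weights)
        # linear-interpolated empirical quantiles shift by O(1/n) under
        # duplication; d itself is size-robust only up to that granularity
        assert rep2.d == pytest.approx(rep.d, rel=0.1)

    def test_invariant_to_cluster_relabeling(self, rng):
        values = rng.normal(0, 1, 80)
        labels = rng.integers(0, 4, 80)
        relabeled = (labels + 2) % 4
        assert csm_weighted_distance(labels, values).d == pytest.approx(
            csm_weighted_distance(relabeled, values).d
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            csm_weighted_distance(np.zeros(10, dtype=int), np.arange(10.0))

    def test_planted_labels_beat_random_labels_on_age(self, planted_dataset):
        _, clinical, labels = planted_dataset
        age = clinical["age"].to_numpy()
        d_planted = csm_weighted_distance(labels, age).d
        rng = np.random.default_rng(0)
        wins = sum(
            d_planted > csm_weighted_distance(rng.permutation(labels), age).d
            for _ in range(50)
        )
        assert wins >= 48

    def test_shape_coupled_covariates_dominate_uncoupled(self, planted_dataset):
        _, clinical, labels = planted_dataset
        table = csm_table(labels, clinical).set_index("variable")["d"]
        assert table["age"] > table["BMI"]
        assert table["age"] > table["BPM"]
        assert table["TT"] > table["BMI"]
        assert table["TT"] > table["BPM"]
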