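"""Class-balancing: K-means, proportional undersampling, SMOTE, Tomek links,
and the split orchestration, each checked against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cluster import KMeans as SkKMeans

from mbtcn.balance import (ClusterConfig, SmoteParams, SplitSpec,
                           balance_dataset, kmeans, largest_remainder,
                           proportional_undersample, remove_links, smote,
                           stratified_split, tomek_links)
from mbtcn.preprocess import BeatMatrix
from mbtcn.synthetic import GeneratorConfig, generate_dataset


def inertia_oracle(X, centroids, assignments):
    """Direct evaluation of the clustering objective (double sum)."""
    return sum(float(np.sum((x - centroids[k]) ** 2))
               for x, k in zip(X, assignments))


class TestKmeans:
    def test_k1_closed_form(self, rng):
        X = rng.standard_normal((40, 5))
        plan = kmeans(X, K=1, seed=0)
        assert np.allclose(plan.centroids[0], X.mean(axis=0))
        assert np.isclose(plan.inertia, np.sum((X - X.mean(0)) ** 2))

    def test_two_separated_clouds_recovered_exactly(self, rng):
        a = rng.normal(-10, 0.1, size=(60, 3))
        b = rng.normal(+10, 0.1, size=(40, 3))
        X = np.vstack([a, b])
        truth = np.array([0] * 60 + [1] * 40)
        plan = kmeans(X, K=2, seed=3)
        # cluster indices are arbitrary: compare the induced partition
        same = plan.assignments == plan.assignments[0]
        assert np.array_equal(same, truth == truth[0])

    def test_inertia_trace_non_increasing_and_matches_oracle(self, rng):
        for seed in range(3):
            X = rng.standard_normal((120, 8))
            plan = kmeans(X, K=5, seed=seed)
            trace = np.array(plan.inertia_trace)
            assert (np.diff(trace) <= 1e-9).all()
            assert np.isclose(plan.inertia,
                              inertia_oracle(X, plan.centroids,
                                             plan.assignments))

    def test_final_inertia_comparable_to_sklearn(self, rng):
        X = rng.standard_normal((200, 6))
        plan = kmeans(X, K=4, seed=0)
        sk = SkKMeans(n_clusters=4, n_init=5, random_state=0).fit(X)
        assert plan.inertia <= sk.inertia_ * 1.25

    def test_k_greater_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans(rng.standard_normal((3, 2)), K=5)


class TestProportionalUndersample:
    def test_identity_when_target_equals_population(self, rng):
        X = rng.standard_normal((50, 4))
        idx, plan = proportional_undersample(X, K=5, n_target=50, seed=0)
        assert np.array_equal(idx, np.arange(50))
        sizes = np.bincount(plan.assignments, minlength=5)
        assert np.array_equal(plan.quotas, sizes)

    def test_quota_arithmetic_600_300_100(self):
        # three well-separated blobs with sizes 600/300/100
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(c, 0.05, size=(n, 2))
                       for c, n in [(0, 600), (100, 300), (200, 100)]])
        idx, plan = proportional_undersample(X, K=3, n_target=100, seed=1)
        assert sorted(plan.quotas.tolist()) == [10, 30, 60]
        assert len(idx) == 100

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=2,
                    max_size=8), st.integers(min_value=0, max_value=100))
    def test_largest_remainder_quotas_sum_exactly(self, sizes, pct):
        total = sum(sizes)
        n_target = min(total, max(1, total * pct // 100))
        quotas = largest_remainder(np.array(sizes), n_target)
        assert quotas.sum() == n_target
        assert (quotas >= 0).all()
        assert (quotas <= np.array(sizes)).all()

    def test_reproducible_under_fixed_seed(self, rng):
        X = rng.standard_normal((80, 6))
        idx1, _ = proportional_undersample(X, K=4, n_target=30, seed=9)
        idx2, _ = proportional_undersample(X, K=4, n_target=30, seed=9)
        assert np.array_equal(idx1, idx2)

    def test_target_above_population_rejected(self, rng):
        with pytest.raises(ValueError):
            proportional_undersample(rng.standard_normal((10, 2)), K=2,
                                     n_target=11)


class TestSmote:
    def test_lambda_endpoints(self, rng):
        X = rng.standard_normal((10, 4))
        new0, d0 = smote(X, SmoteParams(k_neighbors=3, lam_range=(0.0, 0.0),
                                        n_synthetic=5, seed=0),
                         return_details=True)
        assert np.allclose(new0, X[d0["i"]])
        new1, d1 = smote(X, SmoteParams(k_neighbors=3, lam_range=(1.0, 1.0),
                                        n_synthetic=5, seed=0),
                         return_details=True)
        assert np.allclose(new1, X[d1["j"]])

    def test_synthetic_rows_collinear_with_segment(self, rng):
        X = rng.standard_normal((30, 6))
        new, d = smote(X, SmoteParams(k_neighbors=4, n_synthetic=40, seed=1),
                       return_details=True)
        for s, i, j, lam in zip(new, d["i"], d["j"], d["lam"]):
            seg = X[j] - X[i]
            # least-squares projection of (s - x_i) onto the segment
            lam_hat = float(np.dot(s - X[i], seg) / np.dot(seg, seg))
            assert 0.0 <= lam_hat <= 1.0
            assert np.linalg.norm((s - X[i]) - lam_hat * seg) < 1e-9
            assert abs(lam_hat - lam) < 1e-9

    def test_neighbors_are_among_k_nearest(self, rng):
        X = rng.standard_normal((25, 3))
        _new, d = smote(X, SmoteParams(k_neighbors=3, n_synthetic=50, seed=2),
                        return_details=True)
        for i, j in zip(d["i"], d["j"]):
            dist = np.linalg.norm(X - X[i], axis=1)
            dist[i] = np.inf
            assert j in np.argsort(dist, kind="stable")[:3]

    def test_open_interval_never_duplicates_rows(self, rng):
        X = rng.standard_normal((15, 5))
        new = smote(X, SmoteParams(k_neighbors=3, lam_range=(1e-6, 1 - 1e-6),
                                   n_synthetic=100, seed=3))
        for s in new:
            assert not (np.abs(X - s) < 1e-15).all(axis=1).any()

    def test_too_small_minority_rejected_with_hint(self, rng):
        with pytest.raises(ValueError, match="k_neighbors"):
            smote(rng.standard_normal((3, 2)),
                  SmoteParams(k_neighbors=5, n_synthetic=1))


def brute_force_tomek(X, y):
    """O(n^2) oracle: exhaustive mutual-nearest-neighbor search."""
    n = len(X)
    d = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    return [(i, int(nn[i])) for i in range(n)
            if i < nn[i] and nn[nn[i]] == i and y[i] != y[nn[i]]]


class TestTomek:
    def test_single_label_gives_no_links(self, rng):
        X = rng.standard_normal((20, 3))
        assert tomek_links(X, np.array(["A"] * 20)) == []

    def test_1d_toy_example(self):
        X = np.array([[0.0], [1.0], [5.0], [6.0]])
        y = np.array(["A", "B", "B", "A"])
        assert tomek_links(X, y) == [(0, 1), (2, 3)]

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        X = rng.standard_normal((n, 4))
        y = rng.choice(["A", "B", "C"], size=n)
        assert tomek_links(X, y) == brute_force_tomek(X, y)

    def test_majority_member_removed_and_absent_from_output(self, rng):
        X = rng.standard_normal((60, 2))
        y = np.array(["maj"] * 45 + ["min"] * 15)
        links = tomek_links(X, y)
        _Xc, _yc, kept = remove_links(X, y, policy="majority", max_rounds=1)
        removed = set(range(60)) - set(kept.tolist())
        for i, j in links:
            maj = i if y[i] == "maj" else j
            assert maj in removed
        assert removed <= {i for pair in links for i in pair}

    def test_both_policy_removes_both(self, rng):
        X = np.array([[0.0], [0.1], [10.0]])
        y = np.array(["A", "B", "A"])
        _X, _y, kept = remove_links(X, y, policy="both")
        assert kept.tolist() == [2]


class TestBalanceDataset:
    def test_split_arithmetic_80_20_then_80_20(self):
        beats = generate_dataset(
            GeneratorConfig(seed=3,
                            class_proportions=(0.4, 0.15, 0.15, 0.15, 0.15)),
            n=1000)
        beats.synthetic_flags[:] = False
        splits, _rep = balance_dataset(beats, SplitSpec(seed=0),
                                       oversample=False, undersample=False,
                                       tomek_policy=None, seed=0)
        assert len(splits["test"]) == 200
        assert len(splits["val"]) == 160
        assert len(splits["train"]) == 640

    def test_identity_configuration_preserves_counts(self, imbalanced_beats):
        beats = imbalanced_beats.subset(np.arange(len(imbalanced_beats)))
        beats.synthetic_flags[:] = False
        splits, _ = balance_dataset(beats, SplitSpec(seed=1),
                                    oversample=False, undersample=False,
                                    tomek_policy=None, seed=1)
        total = sum(len(s) for s in splits.values())
        assert total == len(beats)

    def test_no_synthetic_rows_in_val_or_test(self, imbalanced_beats):
        beats = imbalanced_beats.subset(np.arange(len(imbalanced_beats)))
        beats.synthetic_flags[:] = False
        for oversample in (True, False):
            splits, rep = balance_dataset(beats, SplitSpec(seed=2),
                                          oversample=oversample, seed=2)
            assert not splits["val"].synthetic_flags.any()
            assert not splits["test"].synthetic_flags.any()
            out = rep["stages"]["output"]
            assert out["synthetic_in_val"] == 0
            assert out["synthetic_in_test"] == 0

    def test_oversampling_confined_to_training_split(self, imbalanced_beats):
        beats = imbalanced_beats.subset(np.arange(len(imbalanced_beats)))
        beats.synthetic_flags[:] = False
        splits, rep = balance_dataset(beats, SplitSpec(seed=4), seed=4)
        added = rep["stages"]["smote"]
        assert splits["train"].synthetic_flags.sum() <= sum(added.values())
        counts = splits["train"].class_counts()
        # minority classes raised toward the median training class size
        assert counts["S"] > rep["stages"]["split"]["train"]["S"]

    def test_reports_identical_under_same_seed(self, imbalanced_beats):
        beats = imbalanced_beats.subset(np.arange(len(imbalanced_beats)))
        beats.synthetic_flags[:] = False
        _s1, rep1 = balance_dataset(beats, SplitSpec(seed=6), seed=6)
        _s2, rep2 = balance_dataset(beats, SplitSpec(seed=6), seed=6)
        assert rep1 == rep2


class TestStratifiedSplit:
    def test_partition_and_stratification(self, imbalanced_beats):
        labels = imbalanced_beats.labels
        rest, held = stratified_split(labels, 0.2, seed=0)
        assert len(set(rest) & set(held)) == 0
        assert len(rest) + len(held) == len(labels)
        for c in "NQ":    # the two largest classes
            frac = (labels[held] == c).sum() / (labels == c).sum()
            assert abs(frac - 0.2) < 0.05
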