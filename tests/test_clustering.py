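import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dsskit.clustering import (
    Partition,
    ResponseProfileClustering,
    dynamic_cut,
    index_difference_permutation_test,
    partition_indices,
    spearman_distance_matrix,
    ward_linkage,
)


def blob_profiles(sizes, rng, n_samples=20, within_sd=0.3):
    """Drug profiles in well-separated correlation blobs; returns (df, truth)."""
    rows, ids, truth = [], [], {}
    for b, size in enumerate(sizes):
        base = rng.normal(0, 1, n_samples)
        for i in range(size):
            rows.append(base + rng.normal(0, within_sd, n_samples))
            ids.append(f"b{b}_{i}")
            truth[f"b{b}_{i}"] = b
    return pd.DataFrame(rows, index=ids), truth


class TestSpearmanDistance:
    def test_identical_profiles_distance_zero(self):
        p = pd.DataFrame([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]], index=["a", "b"])
        d = spearman_distance_matrix(p.astype(float))
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_reversed_ranks_distance_two(self):
        p = pd.DataFrame([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]], index=["a", "b"]).astype(float)
        assert spearman_distance_matrix(p).loc["a", "b"] == pytest.approx(2.0)

    def test_single_inversion_matches_hand_spearman(self):
        # profiles (1,2,3,4,5) vs (1,2,3,5,4): d^2 sum = 2, rho = 1 - 12/120 = 0.9
        p = pd.DataFrame([[1, 2, 3, 4, 5], [1, 2, 3, 5, 4]], index=["a", "b"]).astype(float)
        assert spearman_distance_matrix(p).loc["a", "b"] == pytest.approx(0.1)

    def test_constant_profile_names_drug(self):
        p = pd.DataFrame([[1, 2, 3, 4, 5], [7, 7, 7, 7, 7]], index=["ok", "flat"]).astype(float)
        with pytest.raises(ValueError, match="flat"):
            spearman_distance_matrix(p)

    def test_pairwise_complete_with_missing(self):
        p = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, np.nan], [6, 5, 4, 3, 2, 1]],
            index=["a", "b", "c"],
        )
        d = spearman_distance_matrix(p)
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert d.loc["a", "c"] == pytest.approx(2.0)


class TestWardLinkage:
    def test_nearest_pair_merges_first(self):
        ids = ["x", "y", "z"]
        D = pd.DataFrame([[0, 0.1, 2.0], [0.1, 0, 2.1], [2.0, 2.1, 0]],
                         index=ids, columns=ids)
        dend = ward_linkage(D)
        first = sorted(int(i) for i in dend.linkage[0, :2])
        assert first == [0, 1]  # x and y

    def test_order_permutation_gives_same_tree(self):
        rng = np.random.default_rng(4)
        profiles, _ = blob_profiles([4, 4], rng)
        d1 = spearman_distance_matrix(profiles)
        perm = rng.permutation(profiles.index)
        d2 = spearman_distance_matrix(profiles.loc[perm])
        p1 = dynamic_cut(ward_linkage(d1))
        p2 = dynamic_cut(ward_linkage(d2))
        assert partition_indices(p1, p2)["adjusted_rand"] == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self):
        D = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            ward_linkage(D)

    def test_newick_export_has_all_leaves(self):
        rng = np.random.default_rng(6)
        profiles, _ = blob_profiles([3, 3], rng)
        dend = ward_linkage(spearman_distance_matrix(profiles))
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for leaf in profiles.index:
            assert leaf in nwk


class TestDynamicCut:
    def test_two_blobs_of_ten_recovered(self):
        rng = np.random.default_rng(0)
        profiles, truth = blob_profiles([10, 10], rng)
        part = dynamic_cut(ward_linkage(spearman_distance_matrix(profiles)))
        ref = Partition.from_mapping(truth)
        assert part.n_clusters() == 2
        assert partition_indices(part, ref)["adjusted_rand"] == pytest.approx(1.0)

    def test_equidistant_items_single_cluster(self):
        n = 9
        ids = [f"i{k}" for k in range(n)]
        D = pd.DataFrame(np.ones((n, n)) - np.eye(n), index=ids, columns=ids)
        part = dynamic_cut(ward_linkage(D))
        assert part.n_clusters() == 1

    def test_min_cluster_size_larger_than_n(self):
        ids = ["a", "b", "c"]
        D = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=ids, columns=ids)
        part = dynamic_cut(ward_linkage(D), min_cluster_size=10)
        assert part.n_clusters() == 1

    def test_estimator_interface(self):
        rng = np.random.default_rng(1)
        profiles, truth = blob_profiles([6, 6, 6], rng)
        model = ResponseProfileClustering().fit(profiles)
        assert len(model.labels_) == 18
        ref = Partition.from_mapping(truth)
        assert partition_indices(model.partition_, ref)["adjusted_rand"] > 0.9


def brute_force_indices(a, b):
    """O(n^2) oracle: count pair agreements explicitly."""
    n = len(a)
    s11 = s10 = s01 = s00 = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        s11 += same_a and same_b
        s10 += same_a and not same_b
        s01 += same_b and not same_a
        s00 += not same_a and not same_b
    total = s11 + s10 + s01 + s00
    rand = (s11 + s00) / total
    jacc = s11 / (s11 + s10 + s01) if (s11 + s10 + s01) else 1.0
    fm = s11 / np.sqrt((s11 + s10) * (s11 + s01)) if (s11 + s10) and (s11 + s01) else 0.0
    exp = (s11 + s10) * (s11 + s01) / total
    mx = 0.5 * ((s11 + s10) + (s11 + s01))
    ari = (s11 - exp) / (mx - exp) if mx != exp else 1.0
    return {"rand": rand, "adjusted_rand": ari, "jaccard": jacc, "fowlkes_mallows": fm}


def all_partitions(items):
    """Enumerate every set partition (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def labels_of(partition, items):
    lab = {}
    for k, block in enumerate(partition):
        for item in block:
            lab[item] = k
    return np.array([lab[i] for i in items])


class TestPartitionIndices:
    def test_identical_partitions_all_ones(self):
        p = Partition(("a", "b", "c", "d"), np.array([0, 0, 1, 1]))
        idx = partition_indices(p, p)
        assert all(v == pytest.approx(1.0) for v in idx.values())

    def test_three_item_hand_case(self):
        # P1 = {AB|C}, P2 = {A|BC}: only the AC pair agrees (split in both)
        p1 = Partition(("A", "B", "C"), np.array([0, 0, 1]))
        p2 = Partition(("A", "B", "C"), np.array([0, 1, 1]))
        assert partition_indices(p1, p2)["rand"] == pytest.approx(1 / 3)

    def test_matches_brute_force_over_all_small_partitions(self):
        items = list(range(5))
        parts = [labels_of(p, items) for p in all_partitions(items)]
        rng = np.random.default_rng(0)
        picks = rng.integers(0, len(parts), size=(150, 2))
        ids = tuple("abcde")
        for i, j in picks:
            p1, p2 = Partition(ids, parts[i]), Partition(ids, parts[j])
            got = partition_indices(p1, p2)
            want = brute_force_indices(parts[i], parts[j])
            for k in got:
                assert got[k] == pytest.approx(want[k]), k

    def test_matches_sklearn_on_random_partitions(self):
        from sklearn.metrics import (adjusted_rand_score, fowlkes_mallows_score,
                                     rand_score)
        rng = np.random.default_rng(8)
        ids = tuple(range(30))
        for _ in range(20):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 3, 30)
            got = partition_indices(Partition(ids, a), Partition(ids, b))
            assert got["rand"] == pytest.approx(rand_score(a, b))
            assert got["adjusted_rand"] == pytest.approx(adjusted_rand_score(a, b))
            assert got["fowlkes_mallows"] == pytest.approx(fowlkes_mallows_score(a, b))

    def test_random_partitions_adjusted_rand_near_zero(self):
        rng = np.random.default_rng(15)
        ids = tuple(range(40))
        vals = []
        for _ in range(1000):
            a = rng.integers(0, 4, 40)
            b = rng.integers(0, 4, 40)
            vals.append(partition_indices(Partition(ids, a), Partition(ids, b))["adjusted_rand"])
        assert np.mean(vals) == pytest.approx(0.0, abs=0.01)

    def test_mismatched_item_sets_rejected(self):
        p1 = Partition(("a", "b"), np.array([0, 1]))
        p2 = Partition(("a", "c"), np.array([0, 1]))
        with pytest.raises(ValueError):
            partition_indices(p1, p2)


class TestPermutationTest:
    def make_partitions(self, rng, n=24):
        ids = tuple(f"d{i}" for i in range(n))
        ref = Partition(ids, np.repeat(np.arange(3), n // 3))
        a = Partition(ids, rng.permutation(np.repeat(np.arange(3), n // 3)))
        b = Partition(ids, rng.permutation(np.repeat(np.arange(4), n // 4)))
        return ids, ref, a, b

    def test_equal_partitions_give_central_p(self):
        rng = np.random.default_rng(2)
        ids, ref, a, _ = self.make_partitions(rng)
        out = index_difference_permutation_test(a, a, ref, n_perm=500, seed=1)
        assert (out["difference"] == 0).all()
        assert ((out["p_value"] > 0.2) & (out["p_value"] < 0.8)).all()

    def test_planted_truth_beats_random(self):
        rng = np.random.default_rng(3)
        ids, ref, _, b = self.make_partitions(rng)
        out = index_difference_permutation_test(ref, b, ref, n_perm=2000, seed=5)
        assert (out["p_value"] < 0.01).all()

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(4)
        ids, ref, a, b = self.make_partitions(rng)
        o1 = index_difference_permutation_test(a, b, ref, n_perm=300, seed=9)
        o2 = index_difference_permutation_test(a, b, ref, n_perm=300, seed=9)
        pd.testing.assert_frame_equal(o1, o2)

    def test_small_reference_classes_excluded(self):
        ids = tuple(f"d{i}" for i in range(10))
        # one class of 8, one of 2: the latter is dropped -> < 2 classes left
        ref = Partition(ids, np.array([0] * 8 + [1] * 2))
        a = Partition(ids, np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="classes"):
            index_difference_permutation_test(a, a, ref, n_perm=100, seed=0)

    def test_null_p_values_approximately_uniform(self):
        # both partitions random relative to the reference -> uniform p
        rng = np.random.default_rng(10)
        ids = tuple(f"d{i}" for i in range(24))
        ref = Partition(ids, np.repeat(np.arange(3), 8))
        ps = []
        for rep in range(300):
            a = Partition(ids, rng.permutation(np.repeat(np.arange(3), 8)))
            b = Partition(ids, rng.permutation(np.repeat(np.arange(4), 6)))
            out = index_difference_permutation_test(a, b, ref, n_perm=400,
                                                    seed=int(rng.integers(2**31)))
            ps.append(float(out.set_index("index").loc["adjusted_rand", "p_value"]))
        ks = sps.kstest(ps, "uniform").statistic
        assert ks < 0.08
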