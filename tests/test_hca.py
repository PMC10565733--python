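"""Linkage, W0/W1, threshold nomination, and classification scoring."""

import json

import numpy as np
import pytest

from isoclust import (
    DistanceMatrix,
    classification_score,
    extract_w0_w1,
    isomorphic_threshold,
    linkage_cluster,
    nominate_polymorphs,
)
from tests.oracles import (
    LW_METHODS,
    brute_force_linkage,
    merges_from_dendrogram,
    random_distance_matrix,
)


def dm(values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(labels=[f"p{i}" for i in range(len(values))], values=values)


def two_group_matrix(n_a, n_b, d_within=0.2, d_between=0.8, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    v = np.full((n, n), d_between)
    v[:n_a, :n_a] = d_within
    v[n_a:, n_a:] = d_within
    if jitter:
        noise = rng.normal(0, jitter, (n, n))
        v = v + (noise + noise.T) / 2
    np.fill_diagonal(v, 0.0)
    v = np.clip((v + v.T) / 2, 1e-6, None)
    np.fill_diagonal(v, 0.0)
    return dm(v)


class TestLinkage:
    def test_single_linkage_first_merge_is_closest_pair(self):
        D = dm([[0, 1, 5], [1, 0, 5], [5, 5, 0]])
        tree = linkage_cluster(D, "single")
        merges = merges_from_dendrogram(tree)
        assert merges[0] == (pytest.approx(1.0), frozenset({0, 1}))

    @pytest.mark.parametrize("method", LW_METHODS)
    def test_matches_brute_force_lance_williams(self, method):
        rng = np.random.default_rng(17)
        for trial in range(10):
            D = random_distance_matrix(rng, n=8, euclidean=bool(trial % 2))
            tree = linkage_cluster(dm(D), method)
            got = merges_from_dendrogram(tree)
            want = brute_force_linkage(D, method)
            for (gh, gm), (wh, wm) in zip(got, want):
                assert gh == pytest.approx(wh, abs=1e-9)
                assert gm == wm

    def test_ward_root_children_are_the_two_groups(self):
        tree = linkage_cluster(two_group_matrix(5, 4, jitter=0.02), "ward")
        a, b = tree.children(tree.root_id)
        groups = {tree.members(a), tree.members(b)}
        assert groups == {frozenset(range(5)), frozenset(range(5, 9))}

    def test_ward_heights_monotone(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            D = random_distance_matrix(rng, n=10)
            tree = linkage_cluster(dm(D), "ward")
            assert not tree.has_inversions

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(8)
        D = random_distance_matrix(rng, n=9)
        t1 = linkage_cluster(dm(D), "ward")
        perm = rng.permutation(9)
        Dp = D[np.ix_(perm, perm)]
        t2 = linkage_cluster(
            DistanceMatrix(labels=[f"p{i}" for i in perm], values=Dp), "ward"
        )
        np.testing.assert_allclose(np.sort(t1.Z[:, 2]), np.sort(t2.Z[:, 2]), atol=1e-12)
        assert t1.W0 == pytest.approx(t2.W0)
        assert t1.W1 == pytest.approx(t2.W1)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            linkage_cluster(two_group_matrix(3, 3), "nonsense")


class TestW0W1:
    def test_three_leaf_tree_leaf_child(self):
        # (A,B) merge at 0.1, C joins at 0.8: larger root child is the pair
        D = dm([[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]])
        tree = linkage_cluster(D, "single")
        W0, W1 = extract_w0_w1(tree)
        assert W0 == pytest.approx(0.8)
        assert W1 == pytest.approx(0.1)

    def test_w1_matches_brute_force_on_fixture(self):
        D = random_distance_matrix(np.random.default_rng(23), n=4)
        tree = linkage_cluster(dm(D), "ward")
        merges = brute_force_linkage(D, "ward")
        root_members = merges[-1][1]
        child_heights = [
            h for h, m in merges[:-1]
            if m < root_members and not any(m < m2 for h2, m2 in merges[:-1] if m2 != m)
        ]
        assert tree.W1 == pytest.approx(max(child_heights, default=0.0), abs=1e-9)

    def test_w1_never_exceeds_w0(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            tree = linkage_cluster(dm(random_distance_matrix(rng, n=7)), "ward")
            assert 0.0 <= tree.W1 <= tree.W0 + 1e-12


class TestIsomorphicThreshold:
    def test_printed_trypsin_arithmetic(self):
        assert isomorphic_threshold(1.29, 0.6) == pytest.approx(0.774)
        assert round(isomorphic_threshold(1.29, 0.6), 2) == 0.77
        assert isomorphic_threshold(1.29, 0.7) == pytest.approx(0.903)

    def test_unit_w0_maps_r_to_itself(self):
        assert isomorphic_threshold(1.0, 0.6) == pytest.approx(0.6)
        assert isomorphic_threshold(1.0, 0.7) == pytest.approx(0.7)

    def test_degenerate_and_domain_errors(self):
        assert isomorphic_threshold(0.0, 0.65) == 0.0
        for bad_r in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                isomorphic_threshold(1.0, bad_r)


class TestNominatePolymorphs:
    def test_two_groups_nominated(self):
        tree = linkage_cluster(two_group_matrix(6, 6, jitter=0.02), "ward")
        report = nominate_polymorphs(tree, 0.6, 0.7, min_cluster_fraction=0.05)
        assert len(report.candidate_clusters) == 2
        members = {frozenset(m) for _, m, _ in report.candidate_clusters}
        assert members == {
            frozenset(f"p{i}" for i in range(6)),
            frozenset(f"p{i}" for i in range(6, 12)),
        }

    def test_small_clusters_become_outliers(self):
        # 10 + 2 split: the pair is below min_cluster_fraction = 0.25
        tree = linkage_cluster(two_group_matrix(10, 2, jitter=0.01), "ward")
        report = nominate_polymorphs(tree, 0.6, 0.7, min_cluster_fraction=0.25)
        assert len(report.candidate_clusters) == 1
        assert len(report.outliers) == 1
        assert len(report.outliers[0][1]) == 2

    def test_threshold_interval_recorded(self):
        tree = linkage_cluster(two_group_matrix(4, 4), "ward")
        report = nominate_polymorphs(tree, 0.6, 0.7)
        lo, hi = report.threshold_interval
        assert lo == pytest.approx(0.6 * tree.W0)
        assert hi == pytest.approx(0.7 * tree.W0)

    def test_candidates_are_maximal_and_below_threshold(self):
        rng = np.random.default_rng(4)
        tree = linkage_cluster(dm(random_distance_matrix(rng, n=12)), "ward")
        report = nominate_polymorphs(tree, 0.6, 0.7, min_cluster_fraction=0.0)
        thr = 0.7 * tree.W0
        covered = set()
        for nid, members, h in report.candidate_clusters:
            assert h <= thr
            covered |= set(members)
        assert covered == set(tree.labels)  # maximal nodes partition the leaves


class TestClassificationScore:
    def test_perfect_two_group_tree(self):
        tree = linkage_cluster(two_group_matrix(5, 5, jitter=0.02), "ward")
        labels = ["A"] * 5 + ["B"] * 5
        assert classification_score(tree, labels, k=2) == pytest.approx(1.0)

    def test_one_mislabeled_leaf_of_83(self):
        tree = linkage_cluster(two_group_matrix(42, 41, jitter=0.02, seed=3), "ward")
        labels = ["A"] * 42 + ["B"] * 41
        labels[0] = "B"  # one contaminated label
        assert classification_score(tree, labels, k=2) == pytest.approx(82 / 83)

    def test_random_labels_score_near_half(self):
        rng = np.random.default_rng(12)
        tree = linkage_cluster(two_group_matrix(30, 30, jitter=0.02), "ward")
        scores = []
        for _ in range(50):
            labels = rng.permutation(["A"] * 30 + ["B"] * 30)
            scores.append(classification_score(tree, labels, k=2))
        assert 0.5 <= np.mean(scores) < 0.62

    def test_k_exceeding_leaves_rejected(self):
        tree = linkage_cluster(two_group_matrix(2, 2), "ward")
        with pytest.raises(ValueError):
            classification_score(tree, ["A", "A", "B", "B"], k=5)


class TestExports:
    def test_json_export_is_complete(self):
        tree = linkage_cluster(two_group_matrix(3, 3), "ward")
        d = json.loads(json.dumps(tree.to_dict()))
        assert d["W0"] == pytest.approx(tree.W0)
        assert len(d["nodes"]) == 2 * 6 - 1
        root = next(n for n in d["nodes"] if n["node_id"] == d["root_id"])
        assert sorted(root["members"]) == sorted(tree.labels)

    def test_newick_parses_and_preserves_leaves(self):
        from io import StringIO

        from Bio import Phylo

        tree = linkage_cluster(two_group_matrix(4, 3, jitter=0.01), "ward")
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        names = sorted(t.name for t in parsed.get_terminals())
        assert names == sorted(tree.labels)
        # root-to-leaf depth equals W0 (branch lengths telescope)
        depths = parsed.depths()
        leaf_depths = [d for cl, d in depths.items() if cl.name]
        assert max(leaf_depths) == pytest.approx(tree.W0, abs=1e-6)
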