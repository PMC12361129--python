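import numpy as np
import pytest

from axonfield.labels import expand_region
from axonfield.metrics import (
    aji,
    evaluate_skeletons,
    instances_from_skeletons,
    match_indicator,
    skeleton_scores,
)

from conftest import make_chain


def brute_scores(P, G, thre):
    """Independent O(|P||G|) exhaustive matcher."""
    def matched(q, ref):
        return sum(
            1 for a in q if min(np.linalg.norm(a - b) for b in ref) < thre
        )

    recall = matched(G, P) / len(G)
    precision = matched(P, G) / len(P)
    f1 = 2 * recall * precision / (recall + precision) if recall + precision else 0.0
    return recall, precision, f1


def brute_aji(G_map, P_map):
    """Independent AJI: python sets, explicit greedy pairing."""
    g_ids = sorted(set(G_map.ravel()) - {0})
    p_ids = sorted(set(P_map.ravel()) - {0})
    g_sets = {i: set(map(tuple, np.argwhere(G_map == i))) for i in g_ids}
    p_sets = {j: set(map(tuple, np.argwhere(P_map == j))) for j in p_ids}
    used, inter_sum, union_sum, matched_g = set(), 0, 0, set()
    for gi in g_ids:
        best, best_jac = None, 0.0
        for pj in p_ids:
            if pj in used:
                continue
            inter = len(g_sets[gi] & p_sets[pj])
            union = len(g_sets[gi] | p_sets[pj])
            if union and inter / union > best_jac:
                best, best_jac = pj, inter / union
        if best is not None:
            used.add(best)
            matched_g.add(gi)
            inter_sum += len(g_sets[gi] & p_sets[best])
            union_sum += len(g_sets[gi] | p_sets[best])
    denom = union_sum
    denom += sum(len(g_sets[gi]) for gi in g_ids if gi not in matched_g)
    denom += sum(len(p_sets[pj]) for pj in p_ids if pj not in used)
    return inter_sum / denom if denom else 1.0


class TestMatchIndicator:
    def test_member_point_matches(self):
        G = np.array([[0, 0, 0], [5, 5, 5]])
        assert match_indicator((5, 5, 5), G, 3.0) == 1

    def test_distance_exactly_threshold_is_unmatched(self):
        assert match_indicator((3, 0, 0), np.array([[0, 0, 0]]), 3.0) == 0

    def test_nearby_point_matches(self):
        assert match_indicator((0, 0, 1), np.array([[0, 0, 0]]), 3.0) == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            match_indicator((0, 0, 0), np.empty((0, 3)), 3.0)

    def test_squared_norm_reading(self):
        # distance 2: matched under the Euclidean rule, not under squared (4 >= 3)
        assert match_indicator((2, 0, 0), np.array([[0, 0, 0]]), 3.0) == 1
        assert match_indicator((2, 0, 0), np.array([[0, 0, 0]]), 3.0, squared_norm=True) == 0


class TestSkeletonScores:
    def test_identical_sets_are_perfect(self, rng):
        P = rng.uniform(0, 30, size=(40, 3))
        assert skeleton_scores(P, P.copy()) == (1.0, 1.0, 1.0)

    def test_half_matched_example(self):
        G = np.array([[0, 0, 0], [10, 0, 0]])
        P = np.array([[0, 0, 1], [20, 0, 0]])
        r, p, f1 = skeleton_scores(P, G)
        assert (r, p, f1) == (0.5, 0.5, 0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_matcher(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(0, 20, size=(rng.integers(5, 100), 3))
        G = rng.uniform(0, 20, size=(rng.integers(5, 100), 3))
        got = skeleton_scores(P, G)
        want = brute_scores(P, G, 3.0)
        assert got == pytest.approx(want, abs=1e-12)

    def test_recall_precision_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            P = rng.uniform(0, 15, size=(rng.integers(1, 30), 3))
            G = rng.uniform(0, 15, size=(rng.integers(1, 30), 3))
            r1, p1, _ = skeleton_scores(P, G)
            r2, p2, _ = skeleton_scores(G, P)
            assert r1 == pytest.approx(p2) and p1 == pytest.approx(r2)

    def test_translation_invariance(self, rng):
        P = rng.uniform(0, 10, size=(20, 3))
        G = rng.uniform(0, 10, size=(25, 3))
        shift = np.array([5.5, -3.25, 100.0])
        assert skeleton_scores(P, G) == pytest.approx(skeleton_scores(P + shift, G + shift))

    def test_empty_conventions(self):
        with pytest.warns(UserWarning):
            r, p, f1 = skeleton_scores(np.array([[0.0, 0, 0]]), np.empty((0, 3)))
        assert np.isnan(r)
        assert skeleton_scores(np.empty((0, 3)), np.empty((0, 3))) == (1.0, 1.0, 1.0)


class TestInstances:
    def test_single_tree_labels_its_region_one(self):
        tree = make_chain([(8, 8, 8)])
        labels = instances_from_skeletons([tree], (17, 17, 17), 3.0)
        assert set(np.unique(labels)) == {0, 1}
        assert (labels == 1).sum() == 93

    def test_two_distant_single_point_trees(self):
        a = make_chain([(5, 5, 5)], tree_id=1)
        b = make_chain([(20, 20, 20)], tree_id=2)
        labels = instances_from_skeletons([a, b], (26, 26, 26), 3.0)
        assert (labels == 1).sum() == 93
        assert (labels == 2).sum() == 93

    def test_close_trees_partition_without_overlap(self):
        a = make_chain([(10.0, 10, 10)], tree_id=1)
        b = make_chain([(13.0, 10, 10)], tree_id=2)  # closer than 2 * radius
        labels = instances_from_skeletons([a, b], (21, 21, 21), 3.0)
        region = expand_region([a, b], (21, 21, 21), 3.0)
        assert (labels > 0).sum() == region.sum()  # every region voxel claimed once
        # voxels go to the nearer skeleton
        assert labels[10, 10, 11] == 1 and labels[10, 10, 12] == 2

    def test_ids_contiguous_when_a_tree_is_swallowed(self):
        a = make_chain([(10.0, 10, 10), (11.0, 10, 10)], tree_id=1)
        b = make_chain([(10.5, 10, 10)], tree_id=2)  # strictly farther everywhere? no: swallowed by ties
        c = make_chain([(3.0, 3, 3)], tree_id=3)
        labels = instances_from_skeletons([a, b, c], (21, 21, 21), 3.0)
        present = sorted(set(np.unique(labels)) - {0})
        assert present == list(range(1, len(present) + 1))


class TestAji:
    def test_identical_maps_scores_one(self, rng):
        m = rng.integers(0, 4, size=(10, 10, 10)).astype(np.int32)
        assert aji(m, m) == 1.0

    def test_half_subset_scores_half(self):
        G = np.zeros((10, 10, 10), dtype=int)
        G[:4, :5, :5] = 1  # 100 voxels
        P = np.zeros_like(G)
        P[:2, :5, :5] = 1  # a 50-voxel subset
        assert aji(G, P) == 0.5

    def test_disjoint_instances_score_zero(self):
        G = np.zeros((8, 8, 8), dtype=int)
        P = np.zeros_like(G)
        G[0, 0, :4] = 1
        P[7, 7, :4] = 1
        assert aji(G, P) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        G = rng.integers(0, 4, size=(12, 12, 12)).astype(np.int32)
        P = rng.integers(0, 5, size=(12, 12, 12)).astype(np.int32)
        assert aji(G, P) == pytest.approx(brute_aji(G, P), abs=1e-12)

    def test_score_bounded_in_unit_interval(self, rng):
        G = rng.integers(0, 3, size=(8, 8, 8))
        P = rng.integers(0, 3, size=(8, 8, 8))
        assert 0.0 <= aji(G, P) <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aji(np.zeros((2, 2, 2), int), np.zeros((3, 3, 3), int))


class TestEvaluateSkeletons:
    def test_truth_vs_truth_is_perfect(self, rng):
        pts = np.cumsum(rng.uniform(-1, 1, size=(20, 3)), axis=0) + 16
        trees = [make_chain(pts)]
        report = evaluate_skeletons(trees, trees, (32, 32, 32))
        assert report.recall == 1.0 and report.precision == 1.0 and report.f1 == 1.0
        assert report.aji == 1.0
        assert report.n_g == report.n_p > 0

    def test_rigid_translation_of_both_sides_preserves_scores(self, rng):
        pts = np.cumsum(rng.uniform(-1, 1, size=(15, 3)), axis=0) + 10
        pred = [make_chain(pts + rng.normal(0, 0.5, size=pts.shape))]
        truth = [make_chain(pts)]
        r1 = evaluate_skeletons(pred, truth, (32, 32, 32))
        shift = np.array([3.0, 3.0, 3.0])
        pred2 = [make_chain(t.positions() + shift) for t in pred]
        truth2 = [make_chain(t.positions() + shift) for t in truth]
        r2 = evaluate_skeletons(pred2, truth2, (38, 38, 38))
        assert r2.recall == pytest.approx(r1.recall)
        assert r2.precision == pytest.approx(r1.precision)
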