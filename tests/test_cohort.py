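import numpy as np
import pytest

from graphemd import (
    DistanceMatrix,
    binarize_threshold,
    cohort_summary,
    extract_clusters,
    flag_outliers,
    pairwise_distance_matrix,
    stationary_closed_form,
    w1_flux,
)

from .conftest import random_connected_network, random_profile


def _dm(d, ids=None):
    d = np.asarray(d, dtype=float)
    ids = ids or tuple(f"s{i}" for i in range(d.shape[0]))
    return DistanceMatrix(sample_ids=ids, d=d)


@pytest.fixture(scope="module")
def tiny_cohort():
    """Four random profiles on a small random network, with measures."""
    rng = np.random.default_rng(17)
    net = random_connected_network(rng, 20)
    measures = [
        stationary_closed_form(net, random_profile(rng, net, f"s{i}")) for i in range(4)
    ]
    return net, measures


class TestPairwiseDistanceMatrix:
    def test_identical_profiles_all_zero(self, tiny_cohort):
        net, measures = tiny_cohort
        from graphemd import InvariantMeasure

        clones = [
            InvariantMeasure(sample_id=f"c{i}", pi=measures[0].pi) for i in range(3)
        ]
        dm = pairwise_distance_matrix(net, clones)
        assert np.abs(dm.d).max() <= 1e-9

    def test_entries_match_independent_single_solves(self, tiny_cohort):
        net, measures = tiny_cohort
        dm = pairwise_distance_matrix(net, measures)
        for i in range(4):
            for j in range(i + 1, 4):
                single, _ = w1_flux(net, measures[i], measures[j])
                assert dm.d[i, j] == pytest.approx(single, abs=1e-9)

    def test_permutation_consistency(self, tiny_cohort):
        net, measures = tiny_cohort
        dm = pairwise_distance_matrix(net, measures)
        perm = [2, 0, 3, 1]
        dm_p = pairwise_distance_matrix(net, [measures[i] for i in perm])
        np.testing.assert_allclose(dm_p.d, dm.d[np.ix_(perm, perm)], atol=1e-9)

    def test_validates_symmetry_and_diagonal(self):
        with pytest.raises(ValueError, match="symmetric"):
            _dm([[0, 1], [2, 0]])
        with pytest.raises(ValueError, match="diagonal"):
            _dm([[1, 1], [1, 0]])


class TestBinarize:
    def test_strictly_below_threshold_is_zero(self):
        dm = _dm([[0, 0.074], [0.074, 0]])
        assert binarize_threshold(dm, 0.075)[0, 1] == 0

    def test_at_threshold_is_one(self):
        dm = _dm([[0, 0.075], [0.075, 0]])
        assert binarize_threshold(dm, 0.075)[0, 1] == 1

    def test_zero_matrix_binarizes_to_zero(self):
        dm = _dm(np.zeros((3, 3)))
        assert binarize_threshold(dm, 0.075).sum() == 0

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            binarize_threshold(_dm(np.zeros((2, 2))), 0.0)


class TestExtractClusters:
    def test_two_blocks_split(self):
        d = np.full((4, 4), 1.0)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.01
        np.fill_diagonal(d, 0)
        clusters = extract_clusters(_dm(d), 0.1)
        assert clusters == {"s0": 0, "s1": 0, "s2": 1, "s3": 1}

    def test_threshold_above_max_gives_one_cluster(self):
        rng = np.random.default_rng(0)
        d = rng.random((5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        assert set(extract_clusters(_dm(d), 10.0).values()) == {0}

    def test_threshold_below_min_gives_singletons(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0)
        assert sorted(extract_clusters(_dm(d), 0.01).values()) == [0, 1, 2, 3]

    def test_monotone_in_threshold(self):
        """Raising the threshold only merges components, never splits them."""
        rng = np.random.default_rng(12)
        d = rng.random((8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = _dm(d)
        counts = [
            len(set(extract_clusters(dm, t).values()))
            for t in np.linspace(1e-3, 1.2, 25)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCohortSummary:
    def test_constant_matrix_within_equals_between(self):
        d = np.full((4, 4), 0.3)
        np.fill_diagonal(d, 0)
        s = cohort_summary(_dm(d), {"s0": "x", "s1": "x", "s2": "y", "s3": "y"})
        assert s.within_mean["x"] == pytest.approx(0.3)
        assert s.between_mean == pytest.approx(0.3)

    def test_hand_filled_two_plus_two(self):
        # within x: d01=0.1 ; within y: d23=0.2 ; between: 0.4, 0.5, 0.6, 0.7
        d = np.array(
            [
                [0.0, 0.1, 0.4, 0.5],
                [0.1, 0.0, 0.6, 0.7],
                [0.4, 0.6, 0.0, 0.2],
                [0.5, 0.7, 0.2, 0.0],
            ]
        )
        s = cohort_summary(_dm(d), {"s0": "x", "s1": "x", "s2": "y", "s3": "y"})
        assert s.within_mean["x"] == pytest.approx(0.1)
        assert s.within_mean["y"] == pytest.approx(0.2)
        assert s.between_mean == pytest.approx((0.4 + 0.5 + 0.6 + 0.7) / 4)
        assert s.per_sample_mean["s0"] == pytest.approx((0.1 + 0.4 + 0.5) / 3)

    def test_singleton_group_within_mean_missing(self):
        d = np.full((3, 3), 0.2)
        np.fill_diagonal(d, 0)
        s = cohort_summary(_dm(d), {"s0": "x", "s1": "x", "s2": "lonely"})
        assert s.within_mean["lonely"] is None

    def test_missing_labels_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError, match="labels missing"):
            cohort_summary(_dm(d), {"s0": "x"})


class TestFlagOutliers:
    def test_constant_matrix_flags_nothing(self):
        d = np.full((5, 5), 0.3)
        np.fill_diagonal(d, 0)
        assert flag_outliers(_dm(d)) == []

    def test_planted_far_sample_flagged(self):
        d = np.full((10, 10), 0.1)
        d[9, :] = d[:, 9] = 2.0
        np.fill_diagonal(d, 0)
        assert flag_outliers(_dm(d), k=2.0) == ["s9"]

    def test_unreachable_k_flags_nothing(self):
        rng = np.random.default_rng(4)
        d = rng.random((6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        assert flag_outliers(_dm(d), k=1e9) == []
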