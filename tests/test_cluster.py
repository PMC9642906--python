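import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

import trajclust as tc
from trajclust.cluster import IncomparablePairError

from _oracles import random_euclidean_distance_matrix, ward_agglomerate_oracle

NAN = np.nan


class TestJaccardDistance:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 0, 1], [1, 1, 0], 2 / 3),
            ([1, 0, 1], [1, 0, 1], 0.0),
            ([1, 1, 0, 0], [0, 0, 1, 1], 1.0),          # disjoint supports
            ([1, NAN, 0], [1, 1, NAN], 0.0),            # only bin 0 co-observed
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert tc.jaccard_distance(x, y) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_coobserved_pair_is_maximally_dissimilar(self):
        assert tc.jaccard_distance([0, 0, NAN], [0, NAN, 1]) == 1.0

    def test_no_coobserved_bins_is_an_error(self):
        with pytest.raises(IncomparablePairError):
            tc.jaccard_distance([1, NAN], [NAN, 1])

    binary_row = st.lists(st.sampled_from([0.0, 1.0]), min_size=3, max_size=20)

    @given(st.data())
    @settings(max_examples=300, deadline=None)
    def test_metric_properties_on_complete_rows(self, data):
        n = data.draw(st.integers(3, 16))
        bits = st.lists(st.sampled_from([0.0, 1.0]), min_size=n, max_size=n)
        x = np.array(data.draw(bits))
        y = np.array(data.draw(bits))
        z = np.array(data.draw(bits))
        dxy = tc.jaccard_distance(x, y)
        dyx = tc.jaccard_distance(y, x)
        assert dxy == dyx
        assert 0.0 <= dxy <= 1.0
        if x.any() or y.any():
            # identity of indiscernibles (given a non-empty union of supports)
            assert (dxy == 0.0) == np.array_equal(x, y)
        # triangle inequality
        dxz = tc.jaccard_distance(x, z)
        dzy = tc.jaccard_distance(z, y)
        assert dxy <= dxz + dzy + 1e-12


class TestPairwiseMatrix:
    def test_single_participant(self):
        m = tc.TrajectoryMatrix(["A"], tc.TimeGrid(2010, 1, 3), [[1.0, 0.0, 1.0]])
        d = tc.pairwise_distance_matrix(m)
        assert d.matrix.shape == (1, 1) and d.matrix[0, 0] == 0.0

    def test_matches_scalar_reference(self, rng):
        vals = rng.choice([0.0, 1.0, np.nan], size=(12, 10), p=[0.4, 0.4, 0.2])
        vals[:, 0] = 1.0  # guarantee co-observation
        m = tc.TrajectoryMatrix([f"P{i}" for i in range(12)],
                                tc.TimeGrid(2010, 1, 10), vals)
        d = tc.pairwise_distance_matrix(m)
        np.testing.assert_array_equal(d.matrix, d.matrix.T)
        for i in range(12):
            for j in range(12):
                expected = 0.0 if i == j else tc.jaccard_distance(vals[i], vals[j])
                assert d.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_incomparable_pair_names_participants(self):
        vals = [[1.0, np.nan], [np.nan, 1.0]]
        m = tc.TrajectoryMatrix(["A", "B"], tc.TimeGrid(2010, 1, 2), vals)
        with pytest.raises(IncomparablePairError, match="A.*B"):
            tc.pairwise_distance_matrix(m)


class TestWardAgglomeration:
    def test_three_point_hand_example(self):
        d = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], dtype=float)
        tree = tc.ward_agglomerate(d)
        assert tree.merges[0][:3].tolist() == [0.0, 1.0, 1.0]
        assert tree.merges[1][2] == pytest.approx(np.sqrt(5), abs=1e-12)

    def test_single_point_empty_dendrogram(self):
        tree = tc.ward_agglomerate(np.zeros((1, 1)))
        assert tree.merges.shape == (0, 4)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            tc.ward_agglomerate(np.array([[0, 1], [2, 0]], dtype=float))
        with pytest.raises(ValueError):
            tc.ward_agglomerate(np.array([[0, -1], [-1, 0]], dtype=float))

    @pytest.mark.parametrize("variant", ["ward.D2", "ward.D"])
    def test_matches_recompute_from_scratch_oracle(self, rng, variant):
        for _ in range(25):
            n = int(rng.integers(2, 13))
            D = random_euclidean_distance_matrix(rng, n)
            ours = tc.ward_agglomerate(D, variant=variant).merges
            oracle = ward_agglomerate_oracle(D, variant=variant)
            np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_matches_scipy_ward_heights(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 15))
            D = random_euclidean_distance_matrix(rng, n)
            ours = tc.ward_agglomerate(D).merges
            Z = linkage(squareform(D, checks=False), method="ward")
            np.testing.assert_allclose(np.sort(ours[:, 2]), np.sort(Z[:, 2]),
                                       atol=1e-9)

    def test_merge_heights_monotone(self, rng):
        D = random_euclidean_distance_matrix(rng, 25)
        h = tc.ward_agglomerate(D).merges[:, 2]
        assert np.all(np.diff(h) >= -1e-12)

    def test_tied_distances_merge_deterministically(self):
        D = np.ones((4, 4)) - np.eye(4)
        tree = tc.ward_agglomerate(D)
        assert tree.merges[0][:2].tolist() == [0.0, 1.0]  # smallest id pair first
        tree2 = tc.ward_agglomerate(D)
        np.testing.assert_array_equal(tree.merges, tree2.merges)


class TestCutToK:
    @pytest.fixture()
    def tree(self):
        d = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], dtype=float)
        return tc.ward_agglomerate(d)

    def test_k_extremes(self, tree):
        assert set(tc.cut_to_k(tree, 1)) == {1}
        assert sorted(tc.cut_to_k(tree, 3)) == [1, 2, 3]

    def test_k2_undoes_last_merge(self, tree):
        labels = tc.cut_to_k(tree, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_k_out_of_range(self, tree):
        for k in (0, 4):
            with pytest.raises(ValueError):
                tc.cut_to_k(tree, k)

    def test_labels_ordered_by_positivity(self, tree):
        labels = tc.cut_to_k(tree, 2, positivity=np.array([0.9, 0.8, 0.1]))
        assert labels.tolist() == [2, 2, 1]  # low-activity singleton gets label 1

    def test_cuts_are_nested_refinements(self, rng):
        D = random_euclidean_distance_matrix(rng, 20)
        tree = tc.ward_agglomerate(D)
        for k in range(1, 19):
            coarse = tc.cut_to_k(tree, k)
            fine = tc.cut_to_k(tree, k + 1)
            for lab in np.unique(fine):
                members = coarse[fine == lab]
                assert len(np.unique(members)) == 1


class TestBaselineAndTrends:
    def _matrix(self):
        vals = [[1.0, 0.0], [1.0, 1.0], [0.0, 0.0], [0.0, np.nan]]
        return tc.TrajectoryMatrix(["A", "B", "C", "D"], tc.TimeGrid(2010, 1, 2), vals)

    def test_never_positive_get_label_zero(self):
        m = self._matrix()
        a = tc.assign_baseline_cluster(m, {"A": 1, "B": 2})
        assert a.labels.to_dict() == {"A": 1, "B": 2, "C": 0, "D": 0}
        assert a.k == 2

    def test_overlap_with_baseline_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            tc.assign_baseline_cluster(self._matrix(), {"A": 1, "B": 2, "C": 3})

    def test_unlabelled_positive_participant_rejected(self):
        with pytest.raises(ValueError):
            tc.assign_baseline_cluster(self._matrix(), {"A": 1})

    def test_no_never_participants_leaves_cluster0_empty(self):
        vals = [[1.0, 0.0], [0.0, 1.0]]
        m = tc.TrajectoryMatrix(["A", "B"], tc.TimeGrid(2010, 1, 2), vals)
        a = tc.assign_baseline_cluster(m, {"A": 1, "B": 2})
        assert a.cluster_sizes[0] == 0
        assert len(a.cluster_sizes) == 3  # k+1 label slots

    def test_trend_curves(self):
        m = self._matrix()
        a = tc.assign_baseline_cluster(m, {"A": 1, "B": 1})
        t = tc.cluster_trend_curves(m, a)
        assert t.proportions.loc[1].tolist() == [1.0, 0.5]
        # baseline curve is identically zero where observed
        base = t.proportions.loc[0].to_numpy()
        assert np.nansum(base) == 0.0
        assert t.counts.loc[0].tolist() == [2, 1]

    def test_assignment_must_cover_matrix(self):
        m = self._matrix()
        a = tc.assign_baseline_cluster(m, {"A": 1, "B": 1})
        other = tc.TrajectoryMatrix(["A", "B", "C", "D", "E"],
                                    tc.TimeGrid(2010, 1, 2),
                                    np.zeros((5, 2)))
        with pytest.raises(ValueError):
            tc.cluster_trend_curves(other, a)


class TestRecovery:
    def test_planted_clusters_recovered_single_seed(self):
        profiles = tc.make_default_profiles(3, 32)
        visits, truth = tc.simulate_cohort(profiles, n_participants=300, seed=42)
        flagged = tc.add_behaviour_flags(visits)
        m = tc.bin_to_semiannual(flagged, tc.TimeGrid.default())
        sub = m.subset(m.ever_positive())
        tree = tc.ward_agglomerate(tc.pairwise_distance_matrix(sub))
        labels = tc.cut_to_k(tree, 3, sub.mean_positivity())
        planted = truth.labels_series().reindex(sub.ids)
        assert adjusted_rand_score(planted, labels) >= 0.8


class TestExports:
    def test_dendrogram_csv_and_newick(self, tmp_path):
        d = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], dtype=float)
        tree = tc.ward_agglomerate(d)
        tree.to_csv(tmp_path / "dendro.csv")
        df = pd.read_csv(tmp_path / "dendro.csv")
        assert list(df.columns) == ["step", "left", "right", "height", "size"]
        nwk = tree.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2

    def test_matrix_csv_roundtrip(self, tmp_path):
        vals = [[1.0, np.nan], [0.0, 1.0]]
        m = tc.TrajectoryMatrix(["A", "B"], tc.TimeGrid(2010, 1, 2), vals)
        m.to_csv(tmp_path / "m.csv")
        back = tc.TrajectoryMatrix.from_csv(tmp_path / "m.csv")
        np.testing.assert_array_equal(back.values, m.values)
        assert back.grid.labels == m.grid.labels
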