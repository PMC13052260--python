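"""Resolution-search clustering, downsampling, centroids, z-scoring."""

import numpy as np
import pandas as pd
import pytest

import cytoscore as cs
from cytoscore.clustering import ClusterCentroids
from cytoscore.events import EventMatrix


class TestResolutionSearch:
    def test_recovers_well_separated_blobs(self, blob_data):
        X, y = blob_data
        search = cs.LeidenResolutionSearch(
            target_k=3, r_step=0.1, random_state=0
        ).fit(X)
        assert search.n_clusters_ == 3
        assert cs.adjusted_rand_index(y, search.labels_) >= 0.99
        assert set(search.labels_) == {0, 1, 2}

    def test_chosen_resolution_is_grid_optimal(self, blob_data):
        X, _ = blob_data
        s = cs.LeidenResolutionSearch(target_k=3, r_step=0.1).fit(X)
        best = min(abs(k - 3) for _, k in s.grid_record_)
        chosen = dict(s.grid_record_)[s.resolution_]
        assert abs(chosen - 3) == best
        # tie-break: no smaller grid resolution does as well
        for r, k in s.grid_record_:
            if abs(k - 3) == best:
                assert r >= s.resolution_
                break

    def test_deterministic_under_fixed_seed(self, blob_data):
        X, _ = blob_data
        a = cs.LeidenResolutionSearch(target_k=3, r_step=0.25, random_state=5).fit(X)
        b = cs.LeidenResolutionSearch(target_k=3, r_step=0.25, random_state=5).fit(X)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        assert a.resolution_ == b.resolution_

    def test_identical_events_collapse_to_one_cluster(self):
        X = np.ones((50, 4))
        with pytest.warns(UserWarning, match="identical"):
            s = cs.LeidenResolutionSearch(target_k=3, r_step=0.5).fit(X)
        assert s.n_clusters_ == 1
        assert np.all(s.labels_ == 0)

    def test_achieved_k_trend_is_mostly_nondecreasing(self, blob_data):
        X, _ = blob_data
        s = cs.LeidenResolutionSearch(target_k=3, r_step=0.1).fit(X)
        ks = [k for _, k in s.grid_record_]
        pairs = list(zip(ks, ks[1:]))
        frac = sum(b >= a for a, b in pairs) / len(pairs)
        assert frac >= 0.9

    def test_labels_ordered_by_descending_size(self, blob_data):
        X, _ = blob_data
        s = cs.LeidenResolutionSearch(target_k=3, r_step=0.25).fit(X)
        sizes = np.bincount(s.labels_)
        assert np.all(np.diff(sizes) <= 0)

    def test_more_events_than_target_required(self):
        with pytest.raises(ValueError, match="target_k"):
            cs.LeidenResolutionSearch(target_k=10).fit(np.zeros((5, 2)))


class TestDownsample:
    def matrices(self, sizes):
        rng = np.random.default_rng(0)
        return [
            EventMatrix(values=rng.normal(size=(n, 2)), markers=["A", "B"],
                        sample_id=f"s{i}")
            for i, n in enumerate(sizes)
        ]

    def test_small_group_kept_entirely(self):
        ms = self.matrices([30, 20])
        pooled, prov = cs.downsample_events(ms, ["g1", "g1"], cap=100_000, seed=0)
        assert pooled.shape[0] == 50
        assert len(prov) == 50

    def test_cap_enforced_exactly(self):
        ms = self.matrices([300, 300])
        pooled, prov = cs.downsample_events(ms, ["g1", "g2"], cap=100, seed=0)
        assert pooled.shape[0] == 200
        assert (prov.groupby("group").size() == 100).all()

    def test_same_seed_same_selection(self):
        ms = self.matrices([500])
        _, p1 = cs.downsample_events(ms, ["g"], cap=100, seed=3)
        _, p2 = cs.downsample_events(ms, ["g"], cap=100, seed=3)
        pd.testing.assert_frame_equal(p1, p2)

    def test_provenance_points_to_source_rows(self):
        ms = self.matrices([200])
        pooled, prov = cs.downsample_events(ms, ["g"], cap=50, seed=1)
        np.testing.assert_allclose(pooled, ms[0].values[prov["row"].to_numpy()])


class TestCentroids:
    def test_mean_of_two_events(self):
        c = cs.compute_centroids(np.array([[1.0], [3.0]]), np.array([0, 0]),
                                 markers=["A"])
        assert c.profiles.loc[0, "A"] == 2.0
        assert c.counts[0] == 2

    def test_label_permutation_leaves_rows_identical(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        y = rng.integers(0, 4, 100)
        perm = np.array([2, 0, 3, 1])
        a = cs.compute_centroids(X, y)
        b = cs.compute_centroids(X, perm[y])
        for c in range(4):
            np.testing.assert_allclose(
                a.profiles.loc[c], b.profiles.loc[perm[c]]
            )

    def test_singleton_cluster_equals_event(self):
        X = np.array([[1.0, 2.0], [5.0, 6.0], [5.0, 8.0]])
        c = cs.compute_centroids(X, np.array([0, 1, 1]))
        np.testing.assert_array_equal(c.profiles.loc[0].to_numpy(), X[0])

    def test_empty_cluster_id_warned_and_excluded(self):
        with pytest.warns(UserWarning, match="empty"):
            c = cs.compute_centroids(
                np.zeros((4, 1)), np.array([0, 0, 2, 2]), markers=["A"]
            )
        assert list(c.profiles.index) == [0, 2]

    def test_count_weighted_mean_equals_global_mean(self, blob_data):
        X, y = blob_data
        c = cs.compute_centroids(X, y)
        weighted = (
            c.profiles.mul(c.counts, axis=0).sum() / c.counts.sum()
        ).to_numpy()
        np.testing.assert_allclose(weighted, X.mean(axis=0), atol=1e-9)


class TestZScore:
    def test_two_cluster_hand_computation(self):
        c = ClusterCentroids(
            profiles=pd.DataFrame({"A": [1.0, 3.0]}),
            counts=pd.Series([5, 5]),
        )
        z = cs.zscore_profiles(c)
        np.testing.assert_allclose(
            z.profiles["A"].to_numpy(), [-0.7071067811865475, 0.7071067811865475]
        )

    def test_columns_centred_and_unit_sd(self, blob_data):
        X, y = blob_data
        z = cs.zscore_profiles(cs.compute_centroids(X, y))
        np.testing.assert_allclose(z.profiles.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.profiles.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_constant_marker_dropped_with_warning(self):
        c = ClusterCentroids(
            profiles=pd.DataFrame({"A": [1.0, 3.0], "B": [2.0, 2.0]}),
            counts=pd.Series([1, 1]),
        )
        with pytest.warns(UserWarning, match="constant"):
            z = cs.zscore_profiles(c)
        assert z.markers == ["A"] and z.dropped_markers == ["B"]

    def test_single_cluster_rejected(self):
        c = ClusterCentroids(
            profiles=pd.DataFrame({"A": [1.0]}), counts=pd.Series([1])
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            cs.zscore_profiles(c)
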