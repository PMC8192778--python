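"""Brain-state clustering: vectorization, k selection, assignment."""
import numpy as np
import pandas as pd
import pytest

from rrbdyn.exceptions import ClusteringError, ValidationError
from rrbdyn.states import (BrainStateClustering, assign_states, devectorize, fisher_z,
                           fit_group_states, pair_labels, vectorize_connectivity,
                           vectorize_matrix)
from rrbdyn.windows import TaperKernel, WindowedConnectivity, make_taper


def _wc(subject, mats, names=("A", "B", "C")):
    return WindowedConnectivity(
        subject_id=subject, network_names=tuple(names),
        window_onsets=np.arange(len(mats)), matrices=np.asarray(mats),
        kernel=make_taper(5))


def _random_corrs(rng, n, k=3):
    out = []
    for _ in range(n):
        a = rng.standard_normal((k, k + 2))
        c = np.corrcoef(a)
        out.append(c)
    return np.array(out)


class TestVectorize:
    def test_lower_triangle_order(self):
        m = np.array([[1.0, 0.1, 0.2], [0.1, 1.0, 0.3], [0.2, 0.3, 1.0]])
        assert pair_labels("ABC".__iter__()) == ["B-A", "C-A", "C-B"]
        assert np.allclose(vectorize_matrix(m), [0.1, 0.2, 0.3])

    def test_fisher_z_at_zero(self):
        assert fisher_z(np.array([0.0]))[0] == 0.0

    def test_devectorize_round_trip(self):
        rng = np.random.default_rng(0)
        m = _random_corrs(rng, 1, 5)[0]
        m = np.tril(m, -1) + np.tril(m, -1).T  # exactly symmetric
        np.fill_diagonal(m, 1.0)
        assert np.array_equal(devectorize(vectorize_matrix(m), 5), m)

    def test_frame_layout_and_inconsistent_names(self):
        rng = np.random.default_rng(1)
        wcs = [_wc("s1", _random_corrs(rng, 4)), _wc("s2", _random_corrs(rng, 4))]
        df = vectorize_connectivity(wcs, use_fisher_z=False)
        assert df.shape == (8, 3)
        assert list(df.columns) == ["B-A", "C-A", "C-B"]
        assert df.index[0] == ("s1", 0)
        bad = _wc("s3", _random_corrs(rng, 4), names=("B", "A", "C"))
        with pytest.raises(ValidationError, match="s3"):
            vectorize_connectivity(wcs + [bad])


class TestClustering:
    @staticmethod
    def _two_clouds(rng, n=120, d=12.0):
        centers = np.array([[0.0] * 4, [d] + [0.0] * 3])
        labels = rng.integers(2, size=n)
        return centers[labels] + 0.1 * rng.standard_normal((n, 4)), labels

    def test_separable_clouds_select_k2_with_perfect_labels(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(2)
        X, truth = self._two_clouds(rng)
        est = BrainStateClustering(k_range=(2, 6), n_restarts=10,
                                   random_state=0).fit(X)
        assert est.k_ == 2
        assert adjusted_rand_score(truth, est.labels_) == 1.0
        assert not est.one_state_flag_

    def test_duplicated_rows_get_identical_labels(self):
        rng = np.random.default_rng(3)
        X, _ = self._two_clouds(rng, n=40)
        X2 = np.vstack([X, X])
        est = BrainStateClustering(k_range=(2, 3), n_restarts=5,
                                   random_state=0).fit(X2)
        assert np.array_equal(est.labels_[:40], est.labels_[40:])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((80, 5))
        fits = [BrainStateClustering(k_range=(2, 4), n_restarts=5,
                                     random_state=9).fit(X) for _ in range(2)]
        assert fits[0].k_ == fits[1].k_
        assert np.array_equal(fits[0].labels_, fits[1].labels_)
        assert np.array_equal(fits[0].cluster_centers_, fits[1].cluster_centers_)

    def test_k_capped_by_distinct_rows(self):
        X = np.repeat(np.eye(3), 5, axis=0)  # 3 distinct rows
        est = BrainStateClustering(k_range=(2, 8), n_restarts=3,
                                   random_state=0).fit(X)
        assert est.k_ <= 2  # k_max capped at n_distinct - 1
        with pytest.raises(ClusteringError):
            BrainStateClustering(k_range=(3, 8)).fit(np.repeat(np.eye(2), 4, axis=0))

    def test_silhouette_matches_brute_force(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 4))
        labels = rng.integers(3, size=60)
        d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        vals = []
        for i in range(60):
            own = labels[i]
            a = d[i][(labels == own) & (np.arange(60) != i)].mean()
            b = min(d[i][labels == c].mean() for c in set(labels) if c != own)
            vals.append((b - a) / max(a, b))
        assert abs(np.mean(vals) - silhouette_score(X, labels)) < 1e-10

    def test_single_cluster_data_flags_one_state(self):
        flags = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((150, 6))
            est = BrainStateClustering(k_range=(2, 5), n_restarts=5,
                                       random_state=seed).fit(X)
            flags.append(est.one_state_flag_)
            assert max(est.silhouette_by_k_.values()) < 0.5
        assert all(flags)


class TestAssignment:
    def _model(self):
        rng = np.random.default_rng(6)
        X, _ = TestClustering._two_clouds(rng, n=60)
        feat = pd.DataFrame(X, index=pd.MultiIndex.from_product(
            [["s"], range(60)], names=["subject_id", "window_onset"]))
        return fit_group_states(feat, k_range=(2, 3), n_restarts=5, seed=0), feat

    def test_centroid_maps_to_own_state(self):
        model, feat = self._model()
        cent = pd.DataFrame(model.centroids, index=pd.MultiIndex.from_product(
            [["c"], range(model.k)], names=["subject_id", "window_onset"]))
        pred = assign_states(model, cent)
        assert list(pred) == list(range(1, model.k + 1))

    def test_tie_breaks_toward_lower_state_id(self):
        model, _ = self._model()
        mid = model.centroids.mean(axis=0, keepdims=True)
        # equidistant point between the two centroids
        d = np.linalg.norm(mid - model.centroids, axis=1)
        assert abs(d[0] - d[1]) < 1e-9
        pred = model.estimator.predict(mid)
        assert pred[0] == 0  # 1-based id 1

    def test_training_rows_reproduce_stored_labels(self):
        model, feat = self._model()
        assert (assign_states(model, feat) == model.labels).all()

    def test_dimension_mismatch_rejected(self):
        model, _ = self._model()
        with pytest.raises(ValidationError):
            model.estimator.predict(np.zeros((3, 7)))
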