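"""Tapered sliding-window correlation estimation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrbdyn.exceptions import DegenerateWindowError, InputError, ParameterError
from rrbdyn.simulate import CohortSpec, StateSpec, make_state_correlations, simulate_subject
from rrbdyn.windows import (NetworkTimeSeries, SlidingWindowConnectivity, make_taper,
                            sliding_window_connectivity, weighted_correlation)


def brute_force_weighted_corr(x, w):
    """Direct-summation oracle for the weighted correlation."""
    W, K = x.shape
    mu = np.array([sum(w[j] * x[j, k] for j in range(W)) for k in range(K)])
    cov = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cov[a, b] = sum(w[j] * (x[j, a] - mu[a]) * (x[j, b] - mu[b])
                            for j in range(W))
    corr = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            corr[a, b] = cov[a, b] / np.sqrt(cov[a, a] * cov[b, b])
    return corr


class TestMakeTaper:
    def test_rectangular_is_uniform(self):
        assert np.allclose(make_taper(4, "rectangular").weights, 0.25)

    def test_exponential_small_decay_approaches_uniform(self):
        w = make_taper(10, "exponential", decay_rate=1e-8).weights
        assert np.max(np.abs(w - 0.1)) < 1e-6

    def test_exponential_hand_computed(self):
        w = make_taper(3, "exponential", decay_rate=1.0).weights
        raw = np.array([np.exp(-2), np.exp(-1), 1.0])
        assert np.allclose(w, raw / raw.sum())
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all(np.diff(w) > 0)  # newest sample carries most weight

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_decay_rejected(self, bad):
        with pytest.raises(ParameterError):
            make_taper(5, "exponential", decay_rate=bad)


class TestWeightedCorrelation:
    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(20)
        x = np.column_stack([col, col])
        c = weighted_correlation(x, make_taper(20, "exponential"))
        assert c[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_weights_reduce_to_sample_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 5))
        c = weighted_correlation(x, make_taper(30, "rectangular"))
        assert np.allclose(c, np.corrcoef(x, rowvar=False), atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((50, 4))
        kern = make_taper(50, "exponential")
        c = weighted_correlation(x, kern)
        assert np.max(np.abs(c - brute_force_weighted_corr(x, kern.weights))) < 1e-10

    def test_degenerate_channel_named(self):
        x = np.ones((10, 2))
        x[:, 0] = np.arange(10)
        with pytest.raises(DegenerateWindowError, match="flat"):
            weighted_correlation(x, make_taper(10, "rectangular"),
                                 channel_names=("ok", "flat"))

    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((25, 3))
        kern = make_taper(25, "exponential")
        c0 = weighted_correlation(x, kern)
        x2 = x.copy()
        x2[:, 1] = shift + scale * x2[:, 1]
        assert np.max(np.abs(weighted_correlation(x2, kern) - c0)) < 1e-10


class TestSlidingWindows:
    def test_window_counts(self):
        rng = np.random.default_rng(3)

        def series(T):
            return NetworkTimeSeries("s", ("a", "b"),
                                     rng.standard_normal((T, 2)), 2.0)

        assert sliding_window_connectivity(series(30), make_taper(30), 1).n_windows == 1
        assert sliding_window_connectivity(series(100), make_taper(30), 1).n_windows == 71
        with pytest.raises(InputError):
            sliding_window_connectivity(series(10), make_taper(30), 1)

    def test_matrices_are_valid_correlations(self):
        rng = np.random.default_rng(4)
        ts = NetworkTimeSeries("s", tuple("abcd"), rng.standard_normal((120, 4)), 2.0)
        wc = sliding_window_connectivity(ts, make_taper(20), 3)
        m = wc.matrices
        assert np.max(np.abs(m - m.transpose(0, 2, 1))) < 1e-10
        assert np.allclose(np.einsum("nii->ni", m), 1.0)
        assert np.all(np.abs(m) <= 1.0 + 1e-12)
        for mat in m[::10]:
            assert np.linalg.eigvalsh(mat)[0] > -1e-8

    def test_batched_equals_per_window(self):
        rng = np.random.default_rng(5)
        ts = NetworkTimeSeries("s", tuple("abc"), rng.standard_normal((60, 3)), 2.0)
        kern = make_taper(15)
        wc = sliding_window_connectivity(ts, kern, 2)
        for i, onset in enumerate(wc.window_onsets):
            direct = weighted_correlation(ts.values[onset:onset + 15], kern)
            assert np.max(np.abs(wc.matrices[i] - direct)) < 1e-12

    def test_stationary_series_recovers_generating_correlation(self):
        state = make_state_correlations(1, 6, seed=11)[0]
        spec = CohortSpec(n_per_group=2, n_timepoints=20000, noise_sd=0.0,
                          n_states={"ASD": 1, "TD": 1}, seed=11)
        ts, _ = simulate_subject(spec, "TD", 5,
                                 states=[StateSpec(state.correlation_matrix, 1)])
        wc = sliding_window_connectivity(ts, make_taper(15), 1)
        assert np.max(np.abs(wc.matrices.mean(axis=0)
                             - state.correlation_matrix)) < 0.05


class TestEstimator:
    def test_transformer_converts_seconds_to_samples(self):
        rng = np.random.default_rng(6)
        ts = NetworkTimeSeries("s", ("a", "b"), rng.standard_normal((200, 2)),
                               tr_seconds=2.0)
        est = SlidingWindowConnectivity(window_seconds=30.0)
        wc = est.transform(ts)
        assert wc.kernel.window_samples == 15
        assert wc.n_windows == 200 - 15 + 1

    def test_sklearn_param_interface(self):
        est = SlidingWindowConnectivity(window_seconds=40.0, shape="rectangular")
        assert est.get_params()["window_seconds"] == 40.0
        est.set_params(step=2)
        assert est.step == 2
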