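"""Synthetic cohort generator: states, Markov dynamics, planted effects."""
import numpy as np
import pytest
import scipy.stats
from dataclasses import replace

from rrbdyn.exceptions import GenerationError, ValidationError
from rrbdyn.simulate import (CohortSpec, StateSpec, make_state_correlations,
                             resolve_cohort_spec, simulate_behavior, simulate_cohorts,
                             simulate_item_table, simulate_subject)

from conftest import group_values, windowed_mean_features


class TestStateSpecs:
    def test_single_state_valid(self):
        (s,) = make_state_correlations(1, 4, seed=0)
        assert s.correlation_matrix.shape == (4, 4)

    def test_pairwise_separation_met(self):
        a, b = make_state_correlations(2, 6, separation=0.6, seed=1)
        assert np.linalg.norm(a.correlation_matrix - b.correlation_matrix) >= 0.6

    def test_all_matrices_psd_by_eigendecomposition(self):
        for s in make_state_correlations(4, 4, seed=2):
            evals = np.linalg.eigvalsh(s.correlation_matrix)
            assert evals[0] >= -1e-10
            assert np.allclose(np.diag(s.correlation_matrix), 1.0)

    def test_balanced_set_has_bounded_distance_ratio(self):
        states = make_state_correlations(4, 6, seed=3, balance_ratio=1.35)
        ds = [np.linalg.norm(a.correlation_matrix - b.correlation_matrix)
              for i, a in enumerate(states) for b in states[:i]]
        assert max(ds) / min(ds) <= 1.35

    def test_infeasible_separation_raises(self):
        with pytest.raises(GenerationError):
            make_state_correlations(30, 3, separation=2.0, seed=4, max_tries=50)

    def test_non_psd_state_rejected(self):
        m = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValidationError):
            StateSpec(correlation_matrix=m, label=1)


class TestSubjectSimulation:
    def test_identity_transition_keeps_state_constant(self):
        spec = CohortSpec(n_per_group=2, n_timepoints=200,
                          n_states={"ASD": 2, "TD": 2},
                          transition_matrix={"TD": np.eye(2)}, seed=0)
        states = make_state_correlations(2, 6, seed=0)
        _, gt = simulate_subject(spec, "TD", 9, states=states)
        assert len(np.unique(gt.state_path)) == 1

    def test_deterministic_given_seed(self):
        spec = CohortSpec(n_per_group=2, n_timepoints=150, seed=1)
        states = make_state_correlations(2, 6, seed=1)
        a, _ = simulate_subject(spec, "TD", 4, states=states)
        b, _ = simulate_subject(spec, "TD", 4, states=states)
        assert np.array_equal(a.values, b.values)

    def test_channels_standardized(self):
        spec = CohortSpec(n_per_group=2, n_timepoints=300, seed=2)
        ts, _ = simulate_subject(spec, "ASD", 5)
        assert np.max(np.abs(ts.values.mean(axis=0))) < 1e-10
        assert np.max(np.abs(ts.values.std(axis=0) - 1.0)) < 1e-10

    def test_single_state_sample_correlation_matches_spec(self):
        state = make_state_correlations(1, 6, seed=3)[0]
        spec = CohortSpec(n_per_group=2, n_timepoints=20000, noise_sd=0.0,
                          n_states={"ASD": 1, "TD": 1}, seed=3)
        ts, _ = simulate_subject(spec, "TD", 6, states=[state])
        sample = np.corrcoef(ts.values, rowvar=False)
        assert np.max(np.abs(sample - state.correlation_matrix)) < 0.05

    def test_markov_occupancy_matches_stationary_distribution(self):
        spec = CohortSpec(n_per_group=2, n_timepoints=50000, mean_dwell=20.0,
                          n_states={"ASD": 3, "TD": 3}, seed=4)
        states = make_state_correlations(3, 6, seed=4)
        _, gt = simulate_subject(spec, "TD", 7, states=states)
        counts = np.bincount(gt.state_path - 1, minlength=3)
        # uniform-off-diagonal chain has a uniform stationary distribution;
        # thin by the dwell time so counts are approximately independent
        thinned = gt.state_path[::40] - 1
        c = np.bincount(thinned, minlength=3)
        stat, p = scipy.stats.chisquare(c)
        assert p > 0.01
        assert counts.min() > 0


class TestCohorts:
    def test_group_sizes_and_manifest(self, small_cohort):
        man = small_cohort.manifest
        assert (man["group"] == "ASD").sum() == 10
        assert (man["group"] == "TD").sum() == 10
        assert man["subject_id"].is_unique
        assert len(small_cohort.timeseries) == 20
        assert set(small_cohort.ground_truth.subjects) == set(man["subject_id"])

    def test_cohort_reproducible_from_spec(self):
        spec = CohortSpec(n_per_group=4, n_timepoints=140, seed=11)
        a = simulate_cohorts(spec)
        b = simulate_cohorts(CohortSpec(n_per_group=4, n_timepoints=140, seed=11))
        assert a.manifest.equals(b.manifest)
        for x, y in zip(a.timeseries, b.timeseries):
            assert np.array_equal(x.values, y.values)

    def test_state_counts_follow_spec(self, small_cohort):
        gt = small_cohort.ground_truth
        assert len(gt.states_per_group["ASD"]) == 4
        assert len(gt.states_per_group["TD"]) == 2

    def test_planted_directions_at_study_scale(self):
        """n=48/48: ASD mean CNII lower, mean MNII higher, and the
        state-level CNII variability (SD across true-state means) higher."""
        from rrbdyn.inference import two_sample_test
        from rrbdyn.nii import state_specific_nii, windowed_nii, COGNITIVE_CIRCUIT
        from rrbdyn.windows import make_taper, sliding_window_connectivity

        cohort = simulate_cohorts(CohortSpec(seed=8))
        feats = windowed_mean_features(cohort)
        cn = two_sample_test(*group_values(cohort, feats, "cnii_mean"))
        assert cn.group_means["ASD"] < cn.group_means["TD"]
        mn = two_sample_test(*group_values(cohort, feats, "mnii_mean"))
        assert mn.group_means["ASD"] > mn.group_means["TD"]
        # by-state SD with ground-truth window labels (taper-weighted majority)
        W = cohort.spec.analysis_window_samples
        kern = make_taper(W)
        sds = {"ASD": [], "TD": []}
        for ts in cohort.timeseries:
            gt = cohort.ground_truth.subjects[ts.subject_id]
            wc = sliding_window_connectivity(ts, kern, 1)
            labels = [int(np.argmax(np.bincount(gt.state_path[on:on + W],
                                                weights=kern.weights)))
                      for on in wc.window_onsets]
            per_state = state_specific_nii(windowed_nii(wc, COGNITIVE_CIRCUIT),
                                           labels)
            if len(per_state) > 1:
                sds[gt.group].append(np.std(list(per_state.values()), ddof=1))
        assert np.mean(sds["ASD"]) > np.mean(sds["TD"])

    def test_null_cohorts_center_d_at_zero(self):
        base = resolve_cohort_spec(CohortSpec(
            n_per_group=48, planted_cnii_effect_d=0.0,
            planted_mnii_effect_d=0.0, seed=5))
        ds = []
        for s in range(50):
            cohort = simulate_cohorts(replace(base, seed=600 + s))
            feats = windowed_mean_features(cohort, step=2)
            a, b = group_values(cohort, feats, "cnii_mean")
            from rrbdyn.inference import cohens_d
            ds.append(cohens_d(a, b))
        assert abs(np.mean(ds)) < 0.1


@pytest.fixture(scope="module")
def asd_features():
    import pandas as pd
    rng = np.random.default_rng(12)
    n = 48
    return pd.DataFrame({
        "cnii_mean": rng.standard_normal(n),
        "cnii_sd": rng.standard_normal(n),
        "mnii_mean": rng.standard_normal(n),
    }, index=[f"asd{i:03d}" for i in range(n)])


class TestBehavior:
    def test_item_scores_in_adir_range(self, asd_features):
        spec = CohortSpec(seed=0)
        items, _ = simulate_behavior(asd_features, spec, seed=1)
        assert items.to_numpy().flatten().__len__() == 48 * 9
        assert set(np.unique(items.to_numpy())) <= {0, 1, 2, 3, 6, 7, 8}

    def test_null_behavior_correlation_coverage(self, asd_features):
        spec = CohortSpec(planted_behavior_r=0.0, seed=0)
        inside = 0
        for rep in range(40):
            _, gt = simulate_behavior(asd_features, spec, seed=100 + rep)
            r = np.corrcoef(asd_features["cnii_mean"], gt.factors["CI"])[0, 1]
            inside += abs(r) <= 0.29
        assert inside >= 36  # ~95% coverage of the n=48 null band

    def test_planted_behavior_correlation_positive(self, asd_features):
        spec = CohortSpec(planted_behavior_r=0.5, seed=0)
        pos = 0
        for rep in range(40):
            _, gt = simulate_behavior(asd_features, spec, seed=200 + rep)
            pos += np.corrcoef(asd_features["cnii_mean"],
                               gt.factors["CI"])[0, 1] > 0
        assert pos >= 38

    def test_planted_marginal_correlation_magnitude(self, asd_features):
        spec = CohortSpec(planted_behavior_r=0.4, seed=0)
        rs_mean, rs_sd, rs_rm = [], [], []
        for rep in range(60):
            _, gt = simulate_behavior(asd_features, spec, seed=300 + rep)
            rs_mean.append(np.corrcoef(asd_features["cnii_mean"], gt.factors["CI"])[0, 1])
            rs_sd.append(np.corrcoef(asd_features["cnii_sd"], gt.factors["IS"])[0, 1])
            rs_rm.append(np.corrcoef(asd_features["mnii_mean"], gt.factors["RM"])[0, 1])
        for rs in (rs_mean, rs_sd, rs_rm):
            assert np.mean(rs) == pytest.approx(0.4, abs=0.08)

    def test_missing_feature_rejected(self, asd_features):
        import pandas as pd
        spec = CohortSpec(seed=0)
        broken = asd_features.copy()
        broken.loc[broken.index[0], "cnii_sd"] = np.nan
        with pytest.raises(ValidationError, match="asd000"):
            simulate_behavior(broken, spec, seed=0)


def test_item_table_stand_alone_cohort():
    items, gt = simulate_item_table(n_subjects=126, seed=13)
    assert items.shape == (126, 9)
    assert gt.factors.shape == (126, 3)
    assert set(np.unique(items.to_numpy())) <= {0, 1, 2, 3, 6, 7, 8}
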