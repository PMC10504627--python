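import numpy as np
import pytest

from phenorisk.preprocess import build_daily_features
from phenorisk.synthetic import (ProfileEmission, ScenarioConfig, ScenarioError,
                                 generate_cohort, generate_cohort_truths,
                                 generate_patient, inject_missingness,
                                 sample_feature_matrix, sample_ground_truth,
                                 two_profile_scenario,
                                 weekly_inversion_segments)


class TestConfigValidation:
    def test_distribution_must_sum_to_one(self):
        with pytest.raises(ScenarioError, match="sum to 1"):
            ScenarioConfig(n_true_profiles=2,
                           pattern_segments=[(0, np.array([0.6, 0.5]))])

    def test_segment_starts_strictly_increasing(self):
        with pytest.raises(ScenarioError, match="strictly increasing"):
            ScenarioConfig(n_true_profiles=2, pattern_segments=[
                (0, np.array([0.3, 0.7])), (10, np.array([0.7, 0.3])),
                (10, np.array([0.3, 0.7]))])

    def test_first_segment_at_day_zero(self):
        with pytest.raises(ScenarioError, match="start at day 0"):
            ScenarioConfig(n_true_profiles=2,
                           pattern_segments=[(5, np.array([0.5, 0.5]))])

    def test_rates_in_unit_interval(self):
        with pytest.raises(ScenarioError, match="partial_missing_rate"):
            ScenarioConfig(partial_missing_rate=1.5)

    def test_repeated_distribution_rejected(self):
        with pytest.raises(ScenarioError, match="change point"):
            ScenarioConfig(n_true_profiles=2, pattern_segments=[
                (0, np.array([0.3, 0.7])), (10, np.array([0.3, 0.7]))])


class TestGeneratePatient:
    def test_zero_days_empty(self):
        cfg = two_profile_scenario(change_day=None, days=0)
        stream, truth = generate_patient(cfg, 0)
        assert stream.n_events == 0
        assert truth.n_days == 0
        assert len(truth.change_point_days) == 0

    def test_single_pattern_no_change_points(self, tiny_two_profile_config):
        _, truth = generate_patient(tiny_two_profile_config, 0)
        assert len(truth.change_point_days) == 0

    def test_change_point_recorded(self, split_config):
        truth = sample_ground_truth(split_config, 0)
        assert list(truth.change_point_days) == [60]

    def test_segment_frequencies_match_within_3se(self, split_config):
        # pool several patients so the binomial check has power
        labels = np.concatenate([sample_ground_truth(split_config, i).profile_labels
                                 for i in range(6)])
        n_days = split_config.days_per_patient
        pre = np.concatenate([labels[i * n_days:i * n_days + 60] for i in range(6)])
        post = np.concatenate([labels[i * n_days + 60:(i + 1) * n_days] for i in range(6)])
        for seg, p1 in ((pre, 0.85), (post, 0.15)):
            freq = (seg == 1).mean()
            se = np.sqrt(p1 * (1 - p1) / len(seg))
            assert abs(freq - p1) <= 3 * se

    def test_events_follow_change_points_by_lag(self):
        cfg = two_profile_scenario(change_day=40, days=80, rng_seed=3,
                                   p_event_given_change=1.0, event_lag_days=3)
        truth = sample_ground_truth(cfg, 0)
        assert [e.day for e in truth.events] == [43]

    def test_stream_determinism(self, tiny_two_profile_config):
        s1, t1 = generate_patient(tiny_two_profile_config, 2)
        s2, t2 = generate_patient(tiny_two_profile_config, 2)
        assert s1.gps_fixes == s2.gps_fixes
        assert s1.step_events == s2.step_events
        assert s1.app_events == s2.app_events
        assert np.array_equal(t1.profile_labels, t2.profile_labels)


class TestGenerateCohort:
    def test_empty_cohort(self):
        cfg = two_profile_scenario(change_day=None, days=5, n_patients=0)
        assert generate_cohort(cfg) == []

    def test_same_seed_identical(self):
        cfg = two_profile_scenario(change_day=None, days=4, n_patients=2, rng_seed=9)
        c1 = generate_cohort(cfg)
        c2 = generate_cohort(cfg)
        for (s1, t1), (s2, t2) in zip(c1, c2):
            assert s1.gps_fixes == s2.gps_fixes
            assert np.array_equal(t1.missing, t2.missing)

    def test_event_count_matches_tuned_probability(self):
        # probability tuned so the expected number of patients with an
        # event is 32 out of 225
        cfg = two_profile_scenario(change_day=8, days=20, n_patients=225,
                                   rng_seed=17, p_event_given_change=32 / 225)
        truths = generate_cohort_truths(cfg)
        n_events = sum(1 for t in truths if t.events)
        se = np.sqrt(225 * (32 / 225) * (1 - 32 / 225))
        assert abs(n_events - 32) <= 3 * se


class TestInjectMissingness:
    def test_zero_rates_leave_stream_unchanged(self, tiny_two_profile_config):
        stream, _ = generate_patient(tiny_two_profile_config, 0)
        out, mask = inject_missingness(stream, tiny_two_profile_config, 0)
        assert out.gps_fixes == stream.gps_fixes
        assert out.step_events == stream.step_events
        assert not mask.any()

    def test_total_rate_one_empties_every_day(self):
        cfg = two_profile_scenario(change_day=None, days=5, rng_seed=2,
                                   total_missing_rate=1.0)
        stream, truth = generate_patient(cfg, 0)
        assert stream.n_events == 0
        assert truth.missing.all()

    def test_partial_rate_within_3se(self):
        cfg = two_profile_scenario(change_day=None, days=100, rng_seed=4,
                                   partial_missing_rate=0.2)
        # gps and steps sources are independently dropped at the rate;
        # tally over several patients' plans (500 source-days)
        from phenorisk.synthetic import _sample_missing_plan
        drops = []
        for i in range(5):
            plan = _sample_missing_plan(cfg, i, 100)
            drops.extend([plan[:, 0], plan[:, 2]])
        frac = np.concatenate(drops).mean()
        se = np.sqrt(0.2 * 0.8 / (5 * 2 * 100))
        assert abs(frac - 0.2) <= 3 * se

    def test_total_missing_days_have_no_observations(self):
        cfg = two_profile_scenario(change_day=None, days=20, rng_seed=6,
                                   total_missing_rate=0.3)
        stream, truth = generate_patient(cfg, 1)
        feats = build_daily_features(stream)
        gone = np.flatnonzero(truth.missing.all(axis=1))
        assert len(gone) > 0
        # interior fully-missing days appear as all-missing feature rows
        for d in gone:
            if 0 < d < feats.n_days - 1 and d in feats.days:
                row = np.flatnonzero(feats.days == d)[0]
                assert not feats.mask[row].any()


class TestEmissionRecovery:
    def test_preprocessed_stream_recovers_emission_params(self):
        """Aggregating a rendered stream through preprocessing recovers
        the configured per-profile emission parameters."""
        cfg = two_profile_scenario(change_day=None, days=40, rng_seed=12)
        stream, truth = generate_patient(cfg, 0)
        feats = build_daily_features(stream)
        assert feats.n_days == 40
        for z, prof in enumerate(cfg.profile_emission_params):
            sel = truth.profile_labels == z
            if sel.sum() < 4:
                continue
            assert abs(feats.steps[sel].mean() - prof.steps_log_mean.mean()) < 0.15
            assert abs(feats.app[sel].mean() - prof.app_prob.mean()) < 0.12
            assert abs(feats.home[sel].mean() - prof.home_prob.mean()) < 0.12
            # distance carries a small positive bias on away bins whose
            # sampled target is below the travel overhead; bound it
            bias = feats.distance[sel].mean() - prof.distance_log_mean.mean()
            assert -0.1 < bias < 0.6

    def test_weekly_inversion_segments_shape(self):
        segs = weekly_inversion_segments(60)
        assert segs[0][0] == 0 and segs[1][0] == 60
        np.testing.assert_allclose(segs[0][1], [2 / 7, 5 / 7])
        np.testing.assert_allclose(segs[1][1], [5 / 7, 2 / 7])


class TestSampleFeatureMatrix:
    def test_matches_scenario_shape_and_missingness(self):
        cfg = two_profile_scenario(change_day=None, days=30, rng_seed=8,
                                   total_missing_rate=0.2)
        feats, truth = sample_feature_matrix(cfg, 0)
        assert feats.n_days == 30
        total = truth.missing.all(axis=1)
        assert np.array_equal(feats.fully_missing, total)
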