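"""Generator contracts: exact truth, determinism, calibrated noise."""

import numpy as np
import pytest

from dtuemp.kinematics import compute_angle_sequence
from dtuemp.simulate import (
    CohortSpec,
    TrialSpec,
    generate_cohort,
    generate_trial,
    render_frames,
    render_keypoints,
    truth_track,
)


class TestGenerateTrial:
    def test_zero_variance_gives_exact_cycles(self, clean_trial):
        # 2-s cycles over 20 s at 30 fps: 10 flexion + 10 extension phases,
        # each exactly 1.0 s
        phases = clean_trial.phase_truth
        assert len(phases) == 20
        kinds = [p[0] for p in phases]
        assert kinds == ["flexion", "extension"] * 10
        durations = [(end - start) / clean_trial.spec.fps for _, start, end in phases]
        assert durations == [1.0] * 20
        assert len(clean_trial.theta_true) == 600

    def test_deterministic_given_seed(self):
        spec = TrialSpec(seed=7, cycle_period_sd_s=0.2)
        a, b = generate_trial(spec), generate_trial(spec)
        np.testing.assert_array_equal(a.theta_true, b.theta_true)
        assert a.phase_truth == b.phase_truth

    def test_phases_alternate_and_tile(self):
        trial = generate_trial(TrialSpec(cycle_period_sd_s=0.3, seed=3))
        for (k0, _, e0), (k1, s1, _) in zip(trial.phase_truth, trial.phase_truth[1:]):
            assert k1 != k0
            assert s1 == e0

    def test_cycle_duration_sd_matches_sampling_distribution(self):
        # Monte-Carlo against the stated truncated-normal period model
        target_sd = 0.2
        sds = []
        for seed in range(200):
            trial = generate_trial(TrialSpec(cycle_period_sd_s=target_sd, seed=seed))
            fps = trial.spec.fps
            cycles = [
                (f_end - f_start) / fps + (e_end - e_start) / fps
                for (_, f_start, f_end), (_, e_start, e_end) in zip(
                    trial.phase_truth[::2], trial.phase_truth[1::2]
                )
            ]
            sds.append(np.std(cycles, ddof=1))
        # sample SD of ~10 cycles is biased low (c4 correction) and frame
        # quantisation adds variance; 3 SE band around the target
        se = np.std(sds, ddof=1) / np.sqrt(len(sds))
        assert abs(np.mean(sds) - target_sd) < 3 * se + 0.02

    def test_period_floor_violation_is_an_error(self):
        with pytest.raises(ValueError, match="floor"):
            generate_trial(TrialSpec(cycle_period_mean_s=0.05, cycle_period_sd_s=0.0))


class TestRenderKeypoints:
    def test_noise_free_round_trip(self, clean_trial):
        track = render_keypoints(clean_trial)
        angles = compute_angle_sequence(track)
        np.testing.assert_allclose(angles.values, clean_trial.theta_true, atol=1e-9)

    def test_outlier_count_matches_binomial_expectation(self):
        rate, counts = 0.05, []
        for seed in range(500):
            trial = generate_trial(TrialSpec(outlier_rate=rate, seed=seed))
            track = render_keypoints(trial)
            counts.append(track.flags["wrist"].sum())
        n = 600
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - n * rate) < 3 * se

    def test_outliers_never_consecutive(self):
        for seed in range(50):
            trial = generate_trial(TrialSpec(outlier_rate=0.2, seed=seed))
            track = render_keypoints(trial)
            flagged = np.flatnonzero(track.flags["wrist"])
            assert np.all(np.diff(flagged) >= 2)

    def test_forearm_length_preserved_on_clean_frames(self):
        spec = TrialSpec(jitter_sd_px=2.0, outlier_rate=0.05, seed=4)
        trial = generate_trial(spec)
        track = render_keypoints(trial)
        clean = ~track.flags["wrist"]
        lengths = track.forearm_lengths()[clean]
        assert np.all(np.abs(lengths - spec.forearm_len) < 4 * spec.jitter_sd_px * 2)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TrialSpec(outlier_rate=0.6)
        with pytest.raises(ValueError):
            TrialSpec(angle_min_deg=90, angle_max_deg=10)
        with pytest.raises(ValueError):
            TrialSpec(forearm_len=-1)


class TestRenderFrames:
    @staticmethod
    def _small_track(n=3, wrist=(40.0, 20.0)):
        from dtuemp.pose import TrialTrack

        coords = {
            "elbow": np.tile([32.0, 32.0], (n, 1)),
            "wrist": np.tile(np.asarray(wrist), (n, 1)),
        }
        return TrialTrack(fps=30.0, coords=coords)

    def test_static_track_renders_identical_frames(self):
        stack = render_frames(self._small_track(), size=64, seed=1)
        assert np.array_equal(stack[0], stack[1])
        assert np.array_equal(stack[0], stack[2])

    def test_blob_argmax_marks_keypoint(self):
        track = self._small_track(wrist=(45.0, 18.0))
        stack = render_frames(track, size=64, seed=2)
        frame = stack[0]
        # search the wrist neighbourhood so the elbow blob does not interfere
        region = frame[10:27, 37:54]
        r, c = np.unravel_index(np.argmax(region), region.shape)
        assert abs((37 + c) - 45.0) <= 1 and abs((10 + r) - 18.0) <= 1

    def test_wrist_shift_changes_frames_only_near_wrist(self):
        from dtuemp.pose import TrialTrack

        coords = {
            "elbow": np.array([[32.0, 32.0], [32.0, 32.0]]),
            "wrist": np.array([[45.0, 18.0], [46.0, 18.0]]),
        }
        track = TrialTrack(fps=30.0, coords=coords)
        stack = render_frames(track, size=64, seed=3)
        diff = np.abs(stack[1] - stack[0])
        changed = np.argwhere(diff > 1e-6)
        assert changed.size  # something moved
        assert np.all(np.abs(changed[:, 0] - 18) < 12)
        assert np.all(np.abs(changed[:, 1] - 45.5) < 12)

    def test_out_of_bounds_keypoint_names_frame(self):
        with pytest.raises(ValueError, match="frame 0"):
            render_frames(self._small_track(wrist=(200.0, 10.0)), size=64)

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError, match="48"):
            render_frames(self._small_track(), size=32)


class TestGenerateCohort:
    def test_shape_contract(self):
        cohort = generate_cohort(CohortSpec(n_subjects=20, seed=0))
        assert len(cohort) == 20
        for col in ("subject_id", "age", "sex", "bmi", "mmse", "tug"):
            assert col in cohort.columns
        assert len(CohortSpec().feature_names) == 6
        assert all(f in cohort.columns for f in CohortSpec().feature_names)

    def test_noise_free_outcomes_equal_linear_predictor(self):
        spec = CohortSpec(noise_sd=(0.0, 0.0), seed=1)
        cohort = generate_cohort(spec)
        X = cohort[list(spec.feature_names)].to_numpy()
        w_m = np.asarray(cohort.attrs["w_mmse"])
        w_t = np.asarray(cohort.attrs["w_tug"])
        assert not np.any(cohort["mmse"].isin([0.0, 30.0]))  # no clipping triggered
        np.testing.assert_allclose(cohort["mmse"], spec.outcome_offsets[0] - X @ w_m)
        np.testing.assert_allclose(cohort["tug"], spec.outcome_offsets[1] + X @ w_t)

    def test_support_sign_pattern(self):
        # features in the active support correlate negatively with MMSE and
        # positively with TUG, mirroring slower movement <-> worse status
        corr_m, corr_t = [], []
        for seed in range(200):
            spec = CohortSpec(n_subjects=40, seed=seed)
            cohort = generate_cohort(spec)
            support = cohort.attrs["support"]
            feats = [spec.feature_names[j] for j in support]
            for f in feats:
                corr_m.append(np.corrcoef(cohort[f], cohort["mmse"])[0, 1])
                corr_t.append(np.corrcoef(cohort[f], cohort["tug"])[0, 1])
        assert np.mean(corr_m) < -0.2
        assert np.mean(corr_t) > 0.2
        assert np.mean(np.array(corr_m) < 0) > 0.9
        assert np.mean(np.array(corr_t) > 0) > 0.9

    def test_deterministic(self):
        a = generate_cohort(CohortSpec(seed=5))
        b = generate_cohort(CohortSpec(seed=5))
        assert a.equals(b)

    def test_truth_track_matches_generator(self, clean_trial):
        track = truth_track(clean_trial)
        angles = compute_angle_sequence(track)
        np.testing.assert_allclose(angles.values, clean_trial.theta_true, atol=1e-9)
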