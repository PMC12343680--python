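"""Gait-trial analysis pipeline."""

import numpy as np
import pytest

from fnsgait.gait import (
    LikertResponse,
    compare_conditions,
    ecdf_normal_distance,
    gait_speed_estimate,
    likert_summary,
    lowpass_zero_lag,
    reject_outlier_steps,
    step_metrics,
    stride_normalize_and_ensemble,
    uee_metrics,
)
from fnsgait.synthetic import TrialSpec, generate_trial


class TestFilter:
    def test_constant_signal_unchanged(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass_zero_lag(x, fs=100.0), x, rtol=1e-9)

    def test_cutoff_amplitude_ratio_is_half(self):
        """Forward-backward 2nd-order Butterworth at the cutoff: |H|^2 = 1/2."""
        fs, fc = 100.0, 6.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * fc * t)
        y = lowpass_zero_lag(x, fs, cutoff=fc)
        mid = slice(len(t) // 4, 3 * len(t) // 4)  # avoid edge transients
        ratio = np.abs(y[mid]).max() / np.abs(x[mid]).max()
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_time_reversal_symmetry(self, rng):
        # zero-lag property away from the pad-dominated edges
        x = rng.normal(0, 1, 400)
        fwd = lowpass_zero_lag(x, 100.0)
        rev = lowpass_zero_lag(x[::-1], 100.0)[::-1]
        np.testing.assert_allclose(fwd[50:-50], rev[50:-50], atol=1e-6)

    def test_short_signal_is_named_error(self):
        with pytest.raises(ValueError, match="warm-up"):
            lowpass_zero_lag(np.ones(5), 100.0)


class TestStepMetrics:
    def test_noiseless_recovery_matches_spec_exactly(self):
        """Generator/analyzer round trip: step time, length, swing/stance
        recovered exactly for noiseless synthetic trials."""
        spec = TrialSpec(noise_marker_sd=0.0, noise_force_sd=0.0)
        trial, truth = generate_trial(spec)
        steps = step_metrics(trial)
        assert len(steps) == len(truth)
        by_side = {s: [r for r in steps if r.side == s] for s in ("left", "right")}
        for side in ("left", "right"):
            for rec in by_side[side]:
                assert rec.step_length == pytest.approx(spec.step_length[side],
                                                        abs=1e-9)
            mean_T = np.mean([r.step_time for r in by_side[side]])
            assert mean_T == pytest.approx(spec.step_time[side], abs=0.01)
            for rec in by_side[side]:
                assert rec.swing_stance_ratio == pytest.approx(
                    spec.swing_stance_ratio[side], abs=2e-3)

    def test_swing_stance_ratio_arithmetic(self):
        spec = TrialSpec(step_time={"left": 16.0, "right": 16.0},
                         swing_stance_ratio={"left": 2.0 / 14.0, "right": 2.0 / 14.0})
        trial, _ = generate_trial(spec)
        steps = step_metrics(trial)
        assert steps[0].swing_stance_ratio == pytest.approx(0.1428571, abs=1e-3)

    def test_zero_steps_no_crash(self):
        spec = TrialSpec()
        trial, _ = generate_trial(spec)
        trial.events = {"left": {"footstrike": [], "toeoff": []},
                        "right": {"footstrike": [], "toeoff": []}}
        assert step_metrics(trial) == []


class TestOutliers:
    def _steps(self, n=10):
        spec = TrialSpec(n_steps=n)
        trial, _ = generate_trial(spec)
        return step_metrics(trial)

    def test_identical_steps_none_removed(self):
        steps = self._steps()
        kept, log = reject_outlier_steps(steps)
        assert len(kept) == len(steps)
        assert log == []

    def test_injected_ml_velocity_outlier_removed(self):
        """A step whose ML walker velocity sits at Q3 + 3*IQR of an otherwise
        uniform feature is fenced out (hand-checkable Tukey rule)."""
        steps = self._steps()
        ml = np.linspace(0.04, 0.06, len(steps))  # spread gives a finite IQR
        q1, q3 = np.percentile(ml, [25, 75])
        iqr = q3 - q1
        ml[5] = q3 + 3 * iqr
        kept, log = reject_outlier_steps(steps, ml_velocity=ml)
        assert len(kept) == len(steps) - 1
        assert log[0][0] == 5 and log[0][1] == "ml_walker_velocity"

    def test_fences_computed_once_order_independent(self):
        steps = self._steps()
        ml = np.linspace(0.04, 0.06, len(steps))
        ml[2] = 5.0
        kept1, log1 = reject_outlier_steps(list(steps), ml_velocity=ml)
        order = np.arange(len(steps))[::-1]
        kept2, log2 = reject_outlier_steps([steps[i] for i in order],
                                           ml_velocity=ml[order])
        assert {id(s) for s in kept1} == {id(s) for s in kept2}


class TestEnsemble:
    def test_identical_steps_zero_sd(self):
        t = np.linspace(0, 1, 50)
        v = np.sin(2 * np.pi * t)
        out = stride_normalize_and_ensemble([(t, v)] * 5)
        np.testing.assert_allclose(out["sd"], 0.0, atol=1e-14)
        np.testing.assert_allclose(out["mean"], np.interp(
            np.linspace(0, 100, 101), 100 * t, v), atol=1e-12)

    def test_constant_offset_pair_gives_c_over_sqrt2(self):
        t = np.linspace(0, 1, 50)
        v = np.cos(2 * np.pi * t)
        c = 0.3
        out = stride_normalize_and_ensemble([(t, v), (t, v + c)])
        np.testing.assert_allclose(out["sd"], c / np.sqrt(2), rtol=1e-12)

    def test_time_warped_copies_have_zero_sd(self, rng):
        """Steps of different durations but identical percent-cycle shape."""
        base = np.linspace(0, 1, 200)
        shape = np.sin(2 * np.pi * base) + 0.5 * base
        traces = []
        for dur in (0.8, 1.0, 1.7):
            t = base * dur
            traces.append((t, shape))
        out = stride_normalize_and_ensemble(traces)
        np.testing.assert_allclose(out["sd"], 0.0, atol=1e-12)

    def test_single_step_sd_flagged_nan(self):
        t = np.linspace(0, 1, 10)
        out = stride_normalize_and_ensemble([(t, t)])
        assert np.all(np.isnan(out["sd"]))


class TestGaitSpeed:
    def test_side_averaged_estimates(self):
        # side-averaged step length / step time of slow FNS-assisted stepping
        assert gait_speed_estimate([0.539, 0.538], [16.85, 16.80]) == pytest.approx(
            0.032, abs=5e-4)
        assert gait_speed_estimate([0.556, 0.564], [18.09, 17.82]) == pytest.approx(
            0.031, abs=5e-4)

    def test_zero_length_gives_zero(self):
        assert gait_speed_estimate(0.0, 10.0) == 0.0


class TestUEE:
    def test_constant_force_resultant(self):
        spec = TrialSpec(uee_baseline=100.0,
                         uee_swing_peak={"left": 100.0, "right": 100.0})
        trial, _ = generate_trial(spec)
        # each handle carries (0, 50, 0): summed resultant is 100 N flat
        out = uee_metrics(trial)
        for side in ("left", "right"):
            assert out[side]["cycle_peak"]["mean"] == pytest.approx(100.0, rel=1e-9)
            assert out[side]["cycle_mean"]["mean"] == pytest.approx(100.0, rel=1e-9)

    def test_programmed_swing_peak_recovered(self):
        spec = TrialSpec(uee_baseline=150.0,
                         uee_swing_peak={"left": 300.0, "right": 360.0})
        trial, truth = generate_trial(spec)
        out = uee_metrics(trial)
        assert out["left"]["swing_peak"]["mean"] == pytest.approx(300.0, rel=1e-4)
        assert out["right"]["swing_peak"]["mean"] == pytest.approx(360.0, rel=1e-4)
        # time average of baseline + (peak-baseline) sin^2 over the swing
        assert out["left"]["swing_mean"]["mean"] == pytest.approx(225.0, rel=1e-3)

    def test_missing_channel_is_named_error(self):
        spec = TrialSpec()
        trial, _ = generate_trial(spec)
        trial.handle_forces = {"left": trial.handle_forces["left"], "right": None}
        with pytest.raises(ValueError, match="right handle"):
            uee_metrics(trial)

    def test_zero_forces(self):
        spec = TrialSpec(uee_baseline=1e-12,
                         uee_swing_peak={"left": 1e-12, "right": 1e-12})
        trial, _ = generate_trial(spec)
        out = uee_metrics(trial)
        assert out["left"]["cycle_peak"]["mean"] == pytest.approx(0.0, abs=1e-9)


class TestStatistics:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = compare_conditions(a, list(a), kind="welch_t")
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_welch_matches_hand_computation(self):
        """Textbook two-sample case via the Welch/Satterthwaite formulas."""
        a = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1, 21.9, 22.6])
        b = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0, 24.8, 20.2])
        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (ma - mb) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        res = compare_conditions(a, b, kind="welch_t")
        assert res["statistic"] == pytest.approx(t_hand, abs=1e-6)
        assert res["df"] == pytest.approx(df_hand, abs=1e-6)
        from scipy import stats
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        assert res["p_value"] == pytest.approx(p_hand, abs=1e-6)

    def test_zero_variance_reported_undefined(self):
        res = compare_conditions([1.0, 1.0], [2.0, 2.0], kind="welch_t")
        assert np.isnan(res["statistic"])
        assert "undefined" in res["note"]

    def test_rank_sum_invariant_under_monotone_transform(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 12)
        r1 = compare_conditions(a, b, kind="wilcoxon_rank_sum")
        r2 = compare_conditions(np.exp(a), np.exp(b), kind="wilcoxon_rank_sum")
        assert r1["statistic"] == r2["statistic"]
        assert r1["p_value"] == pytest.approx(r2["p_value"], rel=1e-12)

    def test_likert_summary_median_iqr(self):
        responses = []
        for score in (2, 2, 3, 1, 2):
            responses.append(LikertResponse(1, score, condition="optimized"))
        for score in (1, 2, 1, 1, 0, 2):
            responses.append(LikertResponse(1, score, condition="manual"))
        out = likert_summary(responses)
        assert out["summary"][(1, "optimized")]["median"] == 2.0
        assert out["summary"][(1, "manual")]["median"] == 1.0
        assert 1 in out["rank_sum"]

    def test_likert_validation(self):
        with pytest.raises(ValueError):
            LikertResponse(0, 2)
        with pytest.raises(ValueError):
            LikertResponse(1, 5)

    def test_ecdf_distance_small_for_normal_sample(self, rng):
        x = rng.normal(10, 2, 500)
        assert ecdf_normal_distance(x) < 0.08


class TestNoisyRecovery:
    def test_metrics_within_three_se_over_seeds(self):
        """With measurement noise the mean recovered step length stays within
        3 standard errors of the generator truth over 50 seeds."""
        spec_L = 0.539
        means = []
        for seed in range(50):
            spec = TrialSpec(noise_marker_sd=0.002, n_steps=4, seed=seed)
            trial, _ = generate_trial(spec)
            steps = [s for s in step_metrics(trial) if s.side == "left"]
            means.append(np.mean([s.step_length for s in steps]))
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - spec_L) < 3 * se + 1e-9
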