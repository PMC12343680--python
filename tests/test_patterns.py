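"""Stimulation-pattern compilation, frequency schedules and charge."""

import numpy as np
import pytest

from fnsgait.patterns import (
    ChannelCalibration,
    StimulationPattern,
    build_frequency_schedule,
    charge_per_swing,
    compare_patterns,
    compile_pattern,
    export_patterns,
    extract_swing_excitations,
    import_patterns,
)


def make_calib(group="ta", side="left", sat=200.0, thresh=50.0, amp=20.0,
               method="implanted"):
    return ChannelCalibration(channel=f"{group}_{side[0]}", muscle_group=group,
                              side=side, method=method, sat=sat, thresh=thresh,
                              amplitude=amp)


def make_pattern(pw, duration=1.0, side="left", group="ta", amp=20.0,
                 schedule=None):
    pw = np.asarray(pw, dtype=float)
    if pw.size != 22:
        pw = np.full(22, float(pw))
    return StimulationPattern(
        channel=f"{group}_{side[0]}", side=side, muscle_group=group,
        sample_times=np.linspace(0, duration, 22), pw_us=pw, amplitude_ma=amp,
        frequency_schedule=schedule or [(0.0, duration, 16.0)],
        swing_duration=duration)


class TestCalibration:
    def test_amplitude_limits_by_method(self):
        make_calib(amp=20.0, method="implanted")
        with pytest.raises(ValueError, match="amplitude"):
            make_calib(amp=25.0, method="implanted")
        make_calib(amp=80.0, method="surface")
        with pytest.raises(ValueError, match="amplitude"):
            make_calib(amp=120.0, method="surface")

    def test_thresh_sat_validation(self):
        with pytest.raises(ValueError, match="Thresh"):
            make_calib(thresh=-1.0)
        with pytest.raises(ValueError, match="Sat"):
            make_calib(sat=0.0)


class TestCompile:
    def _compile_single(self, e, side="left", **cal_kw):
        cal = make_calib(side=side, **cal_kw)
        t = np.linspace(0, 1.0, len(np.atleast_1d(e)) if np.ndim(e) else 50)
        e = np.full(t.size, e) if np.ndim(e) == 0 else np.asarray(e)
        pats = compile_pattern({side: {"ta": (t, e)}}, [cal])
        return pats[cal.channel]

    def test_linear_calibration_map(self):
        # excitation 1.0 with Sat 200, Thresh 50 -> 250 µs (right side: no PW gain)
        p = self._compile_single(1.0, side="right", sat=200.0, thresh=50.0)
        assert p.pw_us[0] == pytest.approx(250.0)

    def test_device_limit_clamping(self):
        p = self._compile_single(1.0, side="right", sat=250.0, thresh=50.0)
        np.testing.assert_allclose(p.pw_us, 255.0)

    def test_constant_trace_gives_22_identical_samples(self):
        p = self._compile_single(0.5, side="right", sat=200.0, thresh=50.0)
        assert p.pw_us.shape == (22,)
        np.testing.assert_allclose(p.pw_us, 150.0, rtol=1e-12)

    def test_left_pw_gain_and_reclamp(self):
        p = self._compile_single(1.0, side="left", sat=200.0, thresh=50.0)
        np.testing.assert_allclose(p.pw_us, 255.0)  # 250*1.2 clamped
        p2 = self._compile_single(0.5, side="left", sat=200.0, thresh=50.0)
        np.testing.assert_allclose(p2.pw_us, 150.0 * 1.2, rtol=1e-12)

    def test_right_time_scale_stretched_by_half(self):
        p = self._compile_single(0.5, side="right")
        assert p.swing_duration == pytest.approx(1.5)
        assert p.sample_times[-1] == pytest.approx(1.5)

    def test_resampling_exact_for_affine_and_endpoints(self):
        t = np.linspace(0, 1, 37)
        e = 0.2 + 0.6 * t
        p = compile_pattern({"right": {"ta": (t, e)}}, [make_calib(side="right")])
        pat = p["ta_r"]
        expect = (0.2 + 0.6 * np.linspace(0, 1, 22)) * 200.0 + 50.0
        np.testing.assert_allclose(pat.pw_us, expect, rtol=1e-12)
        assert pat.pw_us[0] == pytest.approx(e[0] * 200 + 50)
        assert pat.pw_us[-1] == pytest.approx(e[-1] * 200 + 50)

    def test_excitation_out_of_range_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            self._compile_single(1.2)


class TestFrequencySchedule:
    def test_left_non_vasti_doubles_after_switch(self):
        sched = build_frequency_schedule("left", "ta_l", 1.0)
        assert sched == [(0.0, 0.15, 16.0), (0.15, 1.0, 32.0)]

    def test_vasti_constant_base_frequency(self):
        for side in ("left", "right"):
            assert build_frequency_schedule(side, "vasti_l", 1.0) == [(0.0, 1.0, 16.0)]

    def test_right_returns_to_base_for_final_30pct(self):
        sched = build_frequency_schedule("right", "ta_r", 1.0)
        assert sched == [(0.0, 0.15, 16.0), (0.15, 0.7, 32.0), (0.7, 1.0, 16.0)]

    def test_short_pattern_single_segment_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            sched = build_frequency_schedule("left", "ta_l", 0.1)
        assert sched == [(0.0, 0.1, 16.0)]
        assert any("never reaches" in r.message for r in caplog.records)


class TestCharge:
    def test_zero_pw_zero_charge(self):
        assert charge_per_swing(make_pattern(0.0)) == 0.0

    def test_constant_pattern_arithmetic(self):
        # 16 pulses x 20 mA x 100 µs = 32 µC over a 1 s swing at 16 Hz
        assert charge_per_swing(make_pattern(100.0)) == pytest.approx(32.0)

    def test_matches_pulse_enumeration_oracle(self, rng):
        """Pulse-by-pulse enumeration oracle (independent interpolation and
        segment walk) on 50 random patterns incl. frequency doubling."""
        for trial in range(50):
            dur = rng.uniform(0.4, 2.5)
            side = ("left", "right")[trial % 2]
            group = ("ta", "vasti", "ilio")[trial % 3]
            pw = rng.uniform(0, 255, 22)
            amp = rng.uniform(1, 20)
            sched = build_frequency_schedule(side, group, dur)
            pat = StimulationPattern(
                channel="c", side=side, muscle_group=group,
                sample_times=np.linspace(0, dur, 22), pw_us=pw,
                amplitude_ma=amp, frequency_schedule=sched, swing_duration=dur)

            def freq_at(t):
                for t0, t1, hz in sched:
                    if t < t1:
                        return hz
                return sched[-1][2]

            def pw_at(t):
                ts = pat.sample_times
                if t <= ts[0]:
                    return pw[0]
                if t >= ts[-1]:
                    return pw[-1]
                i = int(np.searchsorted(ts, t) - 1)
                w = (t - ts[i]) / (ts[i + 1] - ts[i])
                return pw[i] * (1 - w) + pw[i + 1] * w

            charge, t, n = 0.0, 0.0, 0
            while t < dur - 1e-9:
                charge += amp * pw_at(t) * 1e-3
                t += 1.0 / freq_at(t)
                n += 1
            assert charge_per_swing(pat) == pytest.approx(charge, rel=1e-12)

    def test_monotone_in_excitation(self, rng):
        """compile->charge is monotone: raising any excitation sample never
        decreases that channel's charge."""
        t = np.linspace(0, 1, 22)
        e = rng.uniform(0.1, 0.8, 22)
        cal = make_calib(side="left")
        base = charge_per_swing(compile_pattern({"left": {"ta": (t, e)}}, [cal])["ta_l"])
        for j in (0, 7, 21):
            e2 = e.copy()
            e2[j] = min(1.0, e2[j] + 0.15)
            up = charge_per_swing(
                compile_pattern({"left": {"ta": (t, e2)}}, [cal])["ta_l"])
            assert up >= base - 1e-12

    def test_clamping_idempotent(self):
        p = make_pattern(255.0)
        np.testing.assert_allclose(np.clip(p.pw_us, 0, 255), p.pw_us)


class TestCompare:
    charges_opt = {
        "iliopsoas_l": 28.1, "iliopsoas_r": 294.7, "vasti_l": 9.5, "vasti_r": 21.1,
        "ta_l": 17.5, "ta_r": 38.9, "tfl_l": 77.8, "sartorius_r": 948.7,
        "bfsh_r": 94.5,
    }
    charges_man = {
        "iliopsoas_l": 56.0, "iliopsoas_r": 585.0, "vasti_l": 19.2, "vasti_r": 55.0,
        "ta_l": 58.4, "ta_r": 195.0, "tfl_l": 120.0, "sartorius_r": 682.5,
        "bfsh_r": 300.0,
    }

    def test_range_endpoints_and_increase(self):
        rep = compare_patterns(self.charges_opt, self.charges_man)
        # largest reduction: right tibialis anterior 80%
        assert rep.per_muscle["ta_r"]["reduction_pct"] == pytest.approx(80.0, abs=0.5)
        assert rep.max_reduction_pct == pytest.approx(80.0, abs=0.5)
        # smallest reduction: left tensor fasciae latae 35%
        assert rep.per_muscle["tfl_l"]["reduction_pct"] == pytest.approx(35.0, abs=0.5)
        assert rep.min_reduction_pct == pytest.approx(35.0, abs=0.5)
        # right sartorius delivered 39% more charge
        assert rep.increases["sartorius_r"] == pytest.approx(39.0, abs=0.5)

    def test_mean_reduction_over_reduced_muscles(self):
        rep = compare_patterns(self.charges_opt, self.charges_man)
        assert len(rep.per_muscle) - len(rep.increases) == 8
        assert rep.mean_reduction_pct == pytest.approx(58.0, abs=1.0)

    def test_zero_manual_charge_flagged(self):
        rep = compare_patterns({"m": 1.0}, {"m": 0.0})
        assert rep.flagged == ["m"]
        assert rep.per_muscle["m"]["reduction_pct"] is None

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError, match="keys differ"):
            compare_patterns({"a": 1.0}, {"b": 1.0})


class TestExtractAndRoundTrip:
    def test_extract_halves_and_group_average(self, biped):
        from fnsgait.trajectory import Trajectory
        n = 23
        t = np.linspace(0, 2.2, n)
        e = np.full((n, biped.n_mus), 0.01)
        iv = [biped.muscle_index["vasti_med_r"], biped.muscle_index["vasti_lat_r"]]
        e[:, iv[0]] = 0.6
        e[:, iv[1]] = 0.4
        q = np.zeros((n, biped.n_q))
        q[:, 1] = 1.3  # airborne: no stance to trim
        traj = Trajectory(t, biped.coord_names, biped.muscle_names,
                          biped.actuator_names, q, np.zeros((n, biped.n_q)),
                          e.copy(), e, np.zeros((n, biped.n_act)), model=biped)
        out = extract_swing_excitations(traj, model=biped)
        # boundary at half the cycle
        tl, el = out["left"]["vasti_l"]
        assert tl[-1] == pytest.approx(1.1)
        tr, er = out["right"]["vasti_r"]
        assert tr[-1] == pytest.approx(1.1)
        # three-element groups average to a single trace
        np.testing.assert_allclose(er, 0.5, rtol=1e-12)

    def test_symmetric_solution_gives_time_shifted_mirrors(self, biped):
        from fnsgait.trajectory import Trajectory
        n = 41
        t = np.linspace(0, 2.0, n)
        e = np.full((n, biped.n_mus), 0.01)
        phase = t / 2.0
        burst = 0.01 + 0.8 * np.sin(np.pi * np.clip((phase % 1.0) / 0.4, 0, 1)) ** 2
        il, ir = biped.muscle_index["iliopsoas_l"], biped.muscle_index["iliopsoas_r"]
        e[:, il] = burst
        e[:, ir] = np.roll(burst, n // 2)  # half-cycle shift
        e[:, ir] = 0.01 + 0.8 * np.sin(
            np.pi * np.clip(((phase - 0.5) % 1.0) / 0.4, 0, 1)) ** 2
        q = np.zeros((n, biped.n_q))
        q[:, 1] = 1.3
        traj = Trajectory(t, biped.coord_names, biped.muscle_names,
                          biped.actuator_names, q, np.zeros((n, biped.n_q)),
                          e.copy(), e, np.zeros((n, biped.n_act)), model=biped)
        out = extract_swing_excitations(traj, model=biped)
        tl, el = out["left"]["iliopsoas_l"]
        tr, er = out["right"]["iliopsoas_r"]
        np.testing.assert_allclose(el, er, atol=1e-12)

    def test_missing_side_is_named_error(self, double_integrator):
        from fnsgait.trajectory import Trajectory
        t = np.linspace(0, 1, 5)
        traj = Trajectory(t, ["x"], [], ["reserve_x"], np.zeros((5, 1)),
                          np.zeros((5, 1)), np.zeros((5, 0)), np.zeros((5, 0)),
                          np.zeros((5, 1)), model=double_integrator)
        with pytest.raises(ValueError, match="no left-side muscle groups"):
            extract_swing_excitations(traj, model=double_integrator)

    def test_csv_round_trip_reproduces_charge_exactly(self, tmp_path, rng):
        pats = {}
        for side in ("left", "right"):
            pw = rng.uniform(0, 255, 22)
            pats[f"ta_{side[0]}"] = make_pattern(pw, duration=1.3, side=side,
                                                 schedule=build_frequency_schedule(
                                                     side, "ta", 1.3))
        export_patterns(pats, tmp_path)
        back = import_patterns(tmp_path / "pattern.csv", tmp_path / "pattern.json")
        for ch in pats:
            assert charge_per_swing(back[ch]) == charge_per_swing(pats[ch])
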