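"""Cost subterms and their composition."""

import numpy as np
import pytest

from fnsgait.costs import (
    CostWeights,
    MarkerSet,
    ReferenceData,
    compose_cost,
    cost_report,
    eval_aux_deriv,
    eval_contact_tracking,
    eval_effort,
    eval_energy_penalty,
    eval_marker_tracking,
    eval_synergy,
)
from fnsgait.model import Marker, MuscleGroup
from fnsgait.trajectory import Trajectory


def make_traj(time, muscle_names, e, actuator_names=(), r=None, q=None, u=None,
              coord_names=("x",), a=None, tendon=None, model=None):
    n = len(time)
    e = np.asarray(e, dtype=float).reshape(n, len(muscle_names))
    r = (np.zeros((n, len(actuator_names))) if r is None
         else np.asarray(r, dtype=float).reshape(n, len(actuator_names)))
    q = np.zeros((n, len(coord_names))) if q is None else q
    u = np.zeros((n, len(coord_names))) if u is None else u
    a = e.copy() if a is None else a
    return Trajectory(time, list(coord_names), list(muscle_names),
                      list(actuator_names), q, u, a, e, r, tendon_force=tendon,
                      model=model)


def ref_for(biped, time, marker_xy=None, forces=None):
    names = [mk.name for mk in biped.markers]
    if marker_xy is None:
        marker_xy = np.zeros((len(time), len(names), 2))
    if forces is None:
        forces = np.zeros((len(time), 2, 2))
    return ReferenceData(time, names, marker_xy, time, ["left", "right"], forces)


class TestMarkerTracking:
    def test_zero_when_model_matches_reference(self, biped):
        t = np.linspace(0, 1, 11)
        q = np.tile(np.zeros(biped.n_q), (11, 1))
        q[:, biped.coord_index["pelvis_ty"]] = 0.95
        pos = biped.marker_positions(q)
        ref = ref_for(biped, t, marker_xy=pos)
        traj = make_traj(t, biped.muscle_names, np.full((11, biped.n_mus), 0.01),
                         coord_names=biped.coord_names, q=q, model=biped)
        ms = MarkerSet.from_model(biped)
        assert eval_marker_tracking(traj, ref, ms) == pytest.approx(0.0, abs=1e-18)

    def test_constant_offset_single_marker(self, biped):
        """One marker, weight 1, constant 0.1 m error over 1 s -> 0.01; the
        same marker flagged as a bony prominence scores ten-fold."""
        t = np.linspace(0, 1, 21)
        q = np.tile(np.zeros(biped.n_q), (21, 1))
        q[:, 1] = 0.95
        pos = biped.marker_positions(q)
        ref_xy = pos.copy()
        ref_xy[:, 0, 0] += 0.1  # offset the first marker in x
        ref = ref_for(biped, t, marker_xy=ref_xy)
        traj = make_traj(t, biped.muscle_names, np.full((21, biped.n_mus), 0.01),
                         coord_names=biped.coord_names, q=q, model=biped)
        mk = biped.markers[0]
        plain = MarkerSet([Marker(mk.name, mk.segment, mk.offset, 1.0, False)])
        bony = MarkerSet([Marker(mk.name, mk.segment, mk.offset, 10.0, True)])
        assert eval_marker_tracking(traj, ref, plain) == pytest.approx(0.01, rel=1e-12)
        assert eval_marker_tracking(traj, ref, bony) == pytest.approx(0.1, rel=1e-12)

    def test_missing_marker_is_named_error(self, biped):
        t = np.linspace(0, 1, 5)
        ref = ReferenceData(t, ["NOT_A_MARKER"], np.zeros((5, 1, 2)),
                            t, ["left", "right"], np.zeros((5, 2, 2)))
        q = np.tile(np.zeros(biped.n_q), (5, 1))
        q[:, 1] = 0.95
        traj = make_traj(t, biped.muscle_names, np.full((5, biped.n_mus), 0.01),
                         coord_names=biped.coord_names, q=q, model=biped)
        with pytest.raises(KeyError, match="absent in reference"):
            eval_marker_tracking(traj, ref, MarkerSet.from_model(biped))


class TestContactTracking:
    def test_constant_force_error_normalized_by_body_weight(self, biped):
        """1 N error on one foot over 1 s with mg = 747.5 N -> 1/747.5."""
        t = np.linspace(0, 1, 51)
        q = np.tile(np.zeros(biped.n_q), (51, 1))
        q[:, 1] = 1.2  # feet in the air: model contact force ~ 0
        traj = make_traj(t, biped.muscle_names, np.full((51, biped.n_mus), 0.01),
                         coord_names=biped.coord_names, q=q, model=biped)
        forces = np.zeros((51, 2, 2))
        forces[:, 0, 1] = 1.0
        ref = ref_for(biped, t, forces=forces)
        mg = biped.total_mass * biped.gravity
        assert eval_contact_tracking(traj, ref) == pytest.approx(1.0 / mg, rel=1e-5)

    def test_matches_quadrature_oracle_on_random_traces(self, biped, rng):
        t = np.sort(rng.uniform(0, 1, 40))
        t[0], t[-1] = 0.0, 1.0
        q = np.tile(np.zeros(biped.n_q), (40, 1))
        q[:, 1] = 1.2
        traj = make_traj(t, biped.muscle_names, np.full((40, biped.n_mus), 0.01),
                         coord_names=biped.coord_names, q=q, model=biped)
        forces = rng.normal(0, 100, (40, 2, 2))
        ref = ref_for(biped, t, forces=forces)
        totals = biped.foot_contact_totals(q, np.zeros_like(q))
        err2 = np.zeros(40)
        for j, side in enumerate(biped.foot_sides):
            err2 += ((totals[side] - forces[:, j]) ** 2).sum(axis=1)
        oracle = np.trapezoid(err2, t) / (biped.total_mass * biped.gravity)
        assert eval_contact_tracking(traj, ref) == pytest.approx(oracle, rel=1e-10)


class TestSynergy:
    groups = {
        "pair": MuscleGroup("pair", ("m1", "m2"), "left"),
        "triple": MuscleGroup("triple", ("m3", "m4", "m5"), "right"),
    }

    def test_identical_members_cost_zero(self, rng):
        t = np.linspace(0, 1, 11)
        e = np.tile(rng.uniform(0.01, 1, (11, 1)), (1, 5))
        traj = make_traj(t, ["m1", "m2", "m3", "m4", "m5"], e)
        assert eval_synergy(traj, self.groups) == 0.0

    def test_pair_unit_difference_over_one_second(self):
        t = np.linspace(0, 1, 11)
        e = np.column_stack([np.ones(11), np.full(11, 0.01)])
        e[:, 1] = 0.0 + 0.01  # lower bound
        traj = make_traj(t, ["m1", "m2"], e,)
        expected = (1.0 - 0.01) ** 2
        assert eval_synergy(traj, {"pair": self.groups["pair"]}) == pytest.approx(
            expected, rel=1e-12)

    def test_triple_counts_two_difference_terms(self):
        t = np.linspace(0, 1, 11)
        e = np.column_stack([np.ones(11), np.full(11, 0.01), np.full(11, 0.01)])
        traj = make_traj(t, ["m3", "m4", "m5"], e)
        expected = 2 * (1.0 - 0.01) ** 2
        assert eval_synergy(traj, {"triple": self.groups["triple"]}) == pytest.approx(
            expected, rel=1e-12)

    def test_singleton_contributes_zero(self):
        t = np.linspace(0, 1, 5)
        traj = make_traj(t, ["m1"], np.ones((5, 1)))
        g = {"solo": MuscleGroup("solo", ("m1",), "left")}
        assert eval_synergy(traj, g) == 0.0


class TestEffort:
    def test_zero_controls(self):
        t = np.linspace(0, 1, 5)
        traj = make_traj(t, ["m1"], np.full((5, 1), 0.01), actuator_names=["r1"])
        w = CostWeights()
        assert eval_effort(traj, w) == pytest.approx(0.01**2, rel=1e-12)

    @pytest.mark.parametrize("d,expected", [(1.0, 0.25), (2.0, 0.125)])
    def test_distance_normalization(self, d, expected):
        t = np.linspace(0, 1, 21)
        traj = make_traj(t, ["m1"], np.full((21, 1), 0.5))
        w = CostWeights()
        got = eval_effort(traj, w, com_distance=d, divide_by_distance=True)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_invalid_distance_is_error(self):
        t = np.linspace(0, 1, 5)
        traj = make_traj(t, ["m1"], np.full((5, 1), 0.5))
        with pytest.raises(ValueError, match="com_distance"):
            eval_effort(traj, CostWeights(), com_distance=0.0,
                        divide_by_distance=True)

    def test_reserve_channels_penalized_tenfold(self, biped):
        t = np.linspace(0, 1, 11)
        e = np.full((11, biped.n_mus), 0.01)
        r = np.zeros((11, biped.n_act))
        r[:, 0] = 0.5  # pelvis_tx reserve, tagged penalized
        traj = make_traj(t, biped.muscle_names, e,
                         actuator_names=biped.actuator_names, r=r,
                         coord_names=biped.coord_names,
                         q=np.zeros((11, biped.n_q)), u=np.zeros((11, biped.n_q)),
                         model=biped)
        w = CostWeights()
        base = biped.n_mus * 0.01**2
        assert eval_effort(traj, w) == pytest.approx(base + 10.0 * 0.25, rel=1e-9)


class TestEnergyAndAuxDeriv:
    def test_energy_penalty_examples(self):
        t = np.linspace(0, 1, 11)
        traj = make_traj(t, ["rect_abd", "ext_obl"], np.ones((11, 2)))
        assert eval_energy_penalty(traj) == pytest.approx(20.0, rel=1e-12)
        t2 = np.linspace(0, 2, 21)
        e = np.column_stack([np.full(21, 0.5), np.full(21, 0.01)])
        e[:, 1] = 0.01
        traj2 = make_traj(t2, ["rect_abd", "ext_obl"], e)
        assert eval_energy_penalty(traj2) == pytest.approx(
            10 * (0.5**2 + 0.01**2) * 2, rel=1e-12)

    def test_absent_channels_contribute_zero(self):
        t = np.linspace(0, 1, 5)
        traj = make_traj(t, ["vasti_l"], np.ones((5, 1)))
        assert eval_energy_penalty(traj) == 0.0

    def test_aux_deriv_zero_for_constant_and_rigid(self):
        t = np.linspace(0, 1, 11)
        traj = make_traj(t, ["m1"], np.full((11, 1), 0.5))
        assert eval_aux_deriv(traj) == 0.0  # rigid tendon
        traj2 = make_traj(t, ["m1"], np.full((11, 1), 0.5),
                          tendon=np.full((11, 1), 3.0))
        assert eval_aux_deriv(traj2) == pytest.approx(0.0, abs=1e-18)

    def test_aux_deriv_linear_ramp(self):
        t = np.linspace(0, 1, 11)
        traj = make_traj(t, ["m1"], np.full((11, 1), 0.5),
                         tendon=(2.0 * t)[:, None])
        assert eval_aux_deriv(traj) == pytest.approx(4.0, rel=1e-12)


class TestComposition:
    def test_all_zero(self):
        sub = dict(J_mt=0, J_ct=0, J_s=0, J_e=0, J_p=0, J_ad=0)
        assert compose_cost(sub, CostWeights(), "tracking", d=1.0) == 0.0
        assert compose_cost(sub, CostWeights(), "predictive") == 0.0

    def test_tracking_substitution_with_distance(self):
        sub = dict(J_mt=1, J_ct=1, J_s=1, J_e=1, J_p=1, J_ad=1)
        assert compose_cost(sub, CostWeights(), "tracking", d=2.0) == pytest.approx(7.0)

    def test_predictive_substitution(self):
        sub = dict(J_s=1, J_e=1, J_p=1, J_ad=1)
        assert compose_cost(sub, CostWeights(), "predictive") == pytest.approx(4.0)

    def test_tracking_without_reference_subterms_is_error(self):
        with pytest.raises(ValueError, match="tracking composition requires"):
            compose_cost(dict(J_s=1), CostWeights(), "tracking", d=1.0)

    def test_linear_in_subterms_and_weights(self, rng):
        sub = {k: rng.uniform(0, 5) for k in ("J_mt", "J_ct", "J_s", "J_e", "J_p", "J_ad")}
        w = CostWeights(*rng.uniform(0, 2, 6))
        base = compose_cost(sub, w, "tracking", d=1.5)
        sub2 = dict(sub, J_s=2 * sub["J_s"])
        delta = compose_cost(sub2, w, "tracking", d=1.5) - base
        assert delta == pytest.approx(w.w_s * sub["J_s"], rel=1e-12)
        w2 = CostWeights(w.w_mt * 3, w.w_ct, w.w_s, w.w_e, w.w_p, w.w_ad)
        delta_w = compose_cost(sub, w2, "tracking", d=1.5) - base
        assert delta_w == pytest.approx(2 * w.w_mt * sub["J_mt"], rel=1e-12)

    def test_report_structure(self):
        sub = dict(J_s=1.0, J_e=2.0, J_p=0.0, J_ad=0.0)
        rep = cost_report(sub, CostWeights(), "predictive")
        assert rep["total"] == pytest.approx(3.0)
        assert rep["subterms"]["J_e"] == 2.0


class TestQuadratureOracle:
    def test_subterms_match_trapezoid_oracle_on_random_smooth_traces(self, rng):
        """All integral subterms agree with an independent trapezoidal
        quadrature to 1e-10 relative on grid-matched smooth traces."""
        for _ in range(20):
            n = rng.integers(15, 60)
            t = np.sort(rng.uniform(0, 2, n))
            t[0] = 0.0
            e = rng.uniform(0.01, 1.0, (n, 5))
            tendon = rng.normal(0, 10, (n, 2))
            traj = make_traj(t, ["m1", "m2", "m3", "m4", "m5"], e, tendon=tendon)
            groups = {"pair": MuscleGroup("pair", ("m1", "m2"), "left"),
                      "tri": MuscleGroup("tri", ("m3", "m4", "m5"), "right")}
            js = np.trapezoid((e[:, 0] - e[:, 1]) ** 2
                              + (e[:, 2] - e[:, 3]) ** 2 + (e[:, 2] - e[:, 4]) ** 2, t)
            assert eval_synergy(traj, groups) == pytest.approx(js, rel=1e-10)
            je = np.trapezoid((e**2).sum(axis=1), t)
            assert eval_effort(traj, CostWeights()) == pytest.approx(je, rel=1e-10)
            dF = np.gradient(tendon, t, axis=0)
            jad = np.trapezoid((dF**2).sum(axis=1), t)
            assert eval_aux_deriv(traj) == pytest.approx(jad, rel=1e-10)
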