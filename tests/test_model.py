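"""Multibody dynamics of the planar gait model."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fnsgait.contact import ContactSphere
from fnsgait.model import (
    Coordinate,
    MskModel,
    Segment,
    dynamics_residual,
    pendulum_model,
    percent_body_weight,
    planar_biped,
)


def test_fixture_invariants(biped):
    assert biped.total_mass == pytest.approx(76.2)
    assert biped.n_q == 10
    # every muscle in exactly one group, groups of 1-3 members
    members = [m for g in biped.muscle_groups.values() for m in g.members]
    assert sorted(members) == sorted(biped.muscle_names)
    assert all(1 <= len(g.members) <= 3 for g in biped.muscle_groups.values())


def test_group_membership_validation(biped):
    from fnsgait.model import MuscleGroup
    with pytest.raises(ValueError, match="belongs to no group"):
        MskModel(biped.segments, biped.coords, biped.muscles,
                 [MuscleGroup("only", (biped.muscle_names[0],), "left")],
                 biped.contact_spheres, biped.actuators, biped.markers)


class TestStaticEquilibrium:
    def test_hanging_biped_balanced_by_reserve_torques(self, biped):
        """Static pose with feet off the ground: reserve controls computed by
        an independent gravity-lever calculation must zero the residual."""
        q = np.zeros((1, biped.n_q))
        q[0, biped.coord_index["pelvis_ty"]] = 1.2  # feet above the floor
        u = np.zeros_like(q)
        a = np.zeros((1, biped.n_mus))
        e = np.full((1, biped.n_mus), 0.01)

        # Independent lever-arm computation of the gravity torques at q=0:
        # limb segments hang vertically below the hip; only COM x-offsets
        # produce moments.
        g = 9.81
        m_foot, foot_cx = 0.0145 * 76.2, 0.05
        tau_oracle = {c: 0.0 for c in biped.coord_names}
        for side in ("l", "r"):
            for joint in (f"hip_{side}", f"knee_{side}", f"ankle_{side}"):
                tau_oracle[joint] = m_foot * g * foot_cx
        m_pelvis = 0.142 * 76.2
        tau_oracle["pelvis_rot"] = (m_pelvis * g * (-0.02)
                                    + 2 * m_foot * g * foot_cx)
        tau_oracle["pelvis_ty"] = 76.2 * g
        tau_oracle["trunk_pitch"] = 0.0

        r = np.zeros((1, biped.n_act))
        for k, act in enumerate(biped.actuators):
            r[0, k] = tau_oracle[act.target_coordinate] / act.max_magnitude
        mask = np.zeros(biped.n_mus)  # no muscle forces in the balance
        res = dynamics_residual((q, u, a), (u, np.zeros_like(q), np.zeros((1, biped.n_mus))),
                                (e, r), biped, active_muscles=mask)
        assert np.abs(res[0, biped.n_q:2 * biped.n_q]).max() < 1e-6

    def test_doubling_masses_doubles_gravity_residual(self):
        """Force-balance residual of an unbalanced static state is linear in
        the segment masses."""
        m1, m2 = planar_biped(total_mass=76.2), planar_biped(total_mass=152.4)
        q = np.zeros((1, m1.n_q))
        q[0, m1.coord_index["pelvis_ty"]] = 1.25  # no contact
        zeros_q = np.zeros_like(q)
        a = np.zeros((1, m1.n_mus))
        e = np.full((1, m1.n_mus), 0.01)
        r = np.zeros((1, m1.n_act))
        mask = np.zeros(m1.n_mus)
        res1 = dynamics_residual((q, zeros_q, a), (zeros_q, zeros_q, a * 0), (e, r),
                                 m1, active_muscles=mask)
        res2 = dynamics_residual((q, zeros_q, a), (zeros_q, zeros_q, a * 0), (e, r),
                                 m2, active_muscles=mask)
        # atol covers the residual smoothed-contact tail (~1e-7 N), which is
        # mass-independent by construction
        np.testing.assert_allclose(res2[0, m1.n_q:2 * m1.n_q],
                                   2 * res1[0, m1.n_q:2 * m1.n_q],
                                   rtol=1e-9, atol=1e-5)


class TestPendulum:
    def test_small_angle_period_matches_closed_form(self, pendulum):
        """Forward integration of the residual-implied ODE reproduces the
        analytic small-angle period 2*pi*sqrt(L/g) within 1%."""
        L, g = 1.0, 9.81

        def f(t, y):
            ud, _ = pendulum.forward_dynamics([[y[0]]], [[y[1]]], [[0.0]],
                                              [[0.01]], [[0.0]])
            return [y[1], ud[0, 0]]

        T = 2 * np.pi * np.sqrt(L / g)
        sol = solve_ivp(f, [0, T], [0.03, 0.0], rtol=1e-9, atol=1e-11)
        # after one analytic period the angle returns to its start
        assert sol.y[0, -1] == pytest.approx(0.03, rel=1e-2)

    def test_energy_conserved_without_contact(self, pendulum):
        def f(t, y):
            ud, _ = pendulum.forward_dynamics([[y[0]]], [[y[1]]], [[0.0]],
                                              [[0.01]], [[0.0]])
            return [y[1], ud[0, 0]]

        sol = solve_ivp(f, [0, 2.0], [0.8, 0.0], rtol=1e-10, atol=1e-12)
        th, om = sol.y
        E = 0.5 * om**2 - 9.81 * np.cos(th)  # unit mass, unit length
        assert np.ptp(E) < 1e-6


class TestContactDynamics:
    def _ball(self):
        coords = [Coordinate("x", "tx", (-1, 1)), Coordinate("y", "ty", (0, 2))]
        seg = Segment("ball", 1.0, 1e-4, 0.1, parent="ground",
                      coordinates=("x", "y"))
        sph = ContactSphere("ball", (0.0, 0.0), radius=0.1)
        return MskModel([seg], coords, [], [], [sph], [], markers=(),
                        symmetric=False)

    def test_passive_drop_never_gains_energy(self):
        """Dissipative contact: total mechanical energy (kinetic + gravity +
        contact elastic) never increases beyond integration tolerance."""
        m = self._ball()
        sph = m.contact_spheres[0]

        def f(t, y):
            q = y[:2][None, :]
            u = y[2:][None, :]
            ud, _ = m.forward_dynamics(q, u, np.zeros((1, 0)), np.zeros((1, 0)),
                                       np.zeros((1, 0)))
            return np.concatenate([y[2:], ud[0]])

        sol = solve_ivp(f, [0, 1.2], [0.0, 0.4, 0.0, 0.0], rtol=1e-8, atol=1e-10,
                        max_step=1e-3)
        x, y, vx, vy = sol.y
        pen = sph.radius - y
        eps = sph.smoothing
        d_smooth = 0.5 * (pen + np.sqrt(pen**2 + eps**2))
        elastic = sph.stiffness * d_smooth**2.5 / 2.5
        E = 0.5 * (vx**2 + vy**2) + 9.81 * y + elastic
        assert np.max(E - E[0]) < 2e-3 * abs(E[0])  # no spurious energy gain
        assert E[-1] < E[0] - 0.5  # the bounce dissipated energy

    def test_mirrored_state_gives_mirrored_residual(self, biped):
        """Symmetric model: exchanging left/right in the state exchanges the
        left/right components of the dynamics residual exactly."""
        rng = np.random.default_rng(7)
        q = np.zeros((1, biped.n_q))
        q[0] = rng.uniform(-0.2, 0.2, biped.n_q)
        q[0, biped.coord_index["pelvis_ty"]] = 0.97
        u = rng.uniform(-0.5, 0.5, (1, biped.n_q))
        udot = rng.uniform(-2, 2, (1, biped.n_q))
        a = rng.uniform(0, 1, (1, biped.n_mus))
        e = rng.uniform(0.01, 1, (1, biped.n_mus))
        r = np.zeros((1, biped.n_act))
        # restrict to the symmetric muscle subset
        mask = np.array([1.0 if biped.muscle_mirror[i] != i else 0.0
                         for i in range(biped.n_mus)])
        res = dynamics_residual((q, u, a), (u, udot, 0 * a), (e, r), biped,
                                active_muscles=mask)
        qm, um, am = biped.mirror_state(q, u, a)
        udm = udot[:, biped.coord_mirror]
        em = e[:, biped.muscle_mirror]
        resm = dynamics_residual((qm, um, am), (um, udm, 0 * am), (em, r), biped,
                                 active_muscles=mask)
        perm = np.concatenate([biped.coord_mirror, biped.n_q + biped.coord_mirror,
                               2 * biped.n_q + biped.muscle_mirror])
        np.testing.assert_allclose(resm[0], res[0, perm], rtol=1e-9, atol=1e-9)


def test_percent_body_weight():
    assert percent_body_weight(7.7, 76.2) == pytest.approx(1.0, abs=0.05)


def test_singular_configuration_is_diagnosed():
    # a massless, inertia-free segment produces a singular mass matrix
    coords = [Coordinate("theta", "rz", (-3, 3))]
    seg = Segment("rod", 0.0, 0.0, 1.0, parent="ground", com_offset=(0, -1),
                  coordinates=("theta",))
    m = MskModel([seg], coords, [], [], [], [], markers=(), symmetric=False)
    with pytest.raises(RuntimeError, match="singular mass matrix"):
        m.forward_dynamics([[0.1]], [[0.0]], np.zeros((1, 0)), np.zeros((1, 0)),
                           np.zeros((1, 0)))


def test_model_yaml_round_trip(tmp_path, biped):
    from fnsgait.model import load_model, save_model
    path = tmp_path / "model.yaml"
    save_model(biped, path)
    loaded = load_model(path)
    assert loaded.coord_names == biped.coord_names
    assert loaded.muscle_names == biped.muscle_names
    assert loaded.total_mass == pytest.approx(biped.total_mass)
    q = np.full((1, biped.n_q), 0.1)
    q[0, 1] = 0.95
    np.testing.assert_allclose(loaded.marker_positions(q), biped.marker_positions(q))
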