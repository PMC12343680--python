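"""Muscle-actuated planar multibody gait model.

The model is a kinematic tree of rigid segments in the sagittal plane.  The
root segment (pelvis) may carry world-frame translational coordinates plus a
rotation; every other segment attaches to its parent through a revolute joint.
Muscles act through constant moment arms, ground contact through smoothed
Hunt-Crossley spheres, and reserve/joint actuators apply forces or torques
directly to coordinates (representing walker support, volitional effort, and
solver convergence aids).

Dynamics are evaluated in batch: every public routine accepts arrays whose
leading axis enumerates collocation points, so a whole mesh is processed with
a fixed number of numpy operations regardless of mesh size.

The shipped default fixture (:func:`planar_biped`) is a 10-coordinate biped
(pelvis x/y/pitch, trunk pitch, hip/knee/ankle per side) actuated by the
muscle groups an implanted/surface stimulation system can recruit: iliopsoas,
vasti (two elements), and tibialis anterior bilaterally, plus right sartorius,
right biceps femoris short head, and left tensor fasciae latae.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .contact import ContactSphere, contact_force
from .muscle import (
    MuscleTendonUnit,
    _activation_rate,
    active_force_length,
    force_velocity,
    passive_force_length,
)

__all__ = [
    "Coordinate",
    "Segment",
    "Marker",
    "MuscleGroup",
    "ReserveActuator",
    "MskModel",
    "planar_biped",
    "pendulum_model",
    "load_model",
    "save_model",
    "percent_body_weight",
]

GRAVITY = 9.81  # m/s^2


@dataclass
class Coordinate:
    name: str
    kind: str  # "tx" | "ty" | "rz"
    range: tuple = (-10.0, 10.0)  # rad or m
    default_speed_range: tuple = (-20.0, 20.0)

    def __post_init__(self):
        if self.kind not in ("tx", "ty", "rz"):
            raise ValueError(f"coordinate {self.name}: unknown kind {self.kind!r}")
        if not self.range[0] < self.range[1]:
            raise ValueError(f"coordinate {self.name}: empty range {self.range}")


@dataclass
class Segment:
    """Rigid segment.  coordinates lists the joint coordinates (in order of
    application: world translations first, then rotation) that locate this
    segment relative to its parent; only the root may carry translations."""

    name: str
    mass: float  # kg
    inertia: float  # kg m^2 about the COM, planar
    length: float  # m, bookkeeping / display
    parent: str  # parent segment name, or "ground"
    parent_offset: tuple = (0.0, 0.0)  # joint anchor in parent frame, m
    com_offset: tuple = (0.0, 0.0)  # COM in local frame, m
    coordinates: tuple = ()  # coordinate names

    def __post_init__(self):
        if self.mass < 0 or self.inertia < 0:
            raise ValueError(f"segment {self.name}: negative mass/inertia")


@dataclass
class Marker:
    name: str
    segment: str
    offset: tuple  # m, local frame
    weight: float = 1.0
    bony_prominence: bool = False


@dataclass
class MuscleGroup:
    """A stimulation channel's muscle group: 1-3 muscle elements driven by a
    single excitation channel (synergy is encouraged, not hard-wired)."""

    gid: str
    members: tuple  # muscle names
    side: str  # "left" | "right"
    method: str = "implanted"  # "implanted" | "surface"

    def __post_init__(self):
        if not 1 <= len(self.members) <= 3:
            raise ValueError(f"group {self.gid}: needs 1-3 members, got {len(self.members)}")


@dataclass
class ReserveActuator:
    target_coordinate: str
    kind: str  # "force" | "torque"
    max_magnitude: float  # N or Nm
    cost_weight_tag: str = "penalized"  # "normal" | "penalized"
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("force", "torque"):
            raise ValueError(f"actuator on {self.target_coordinate}: bad kind {self.kind!r}")
        if not self.max_magnitude > 0:
            raise ValueError(f"actuator on {self.target_coordinate}: max_magnitude must be > 0")
        if not self.name:
            self.name = f"reserve_{self.target_coordinate}"


@dataclass
class LegLandmarks:
    """Paired points used by the leg-clearance constraint.  lateral offsets
    give each point a fixed out-of-plane position (m) in the planar model."""

    left_segment: str = ""
    left_offset: tuple = (0.0, 0.0)
    left_lateral: float = 0.1
    right_segment: str = ""
    right_offset: tuple = (0.0, 0.0)
    right_lateral: float = -0.1


class MskModel:
    """Assembled model: linkage + muscles + contact + actuators + markers."""

    def __init__(
        self,
        segments,
        coordinates,
        muscles,
        muscle_groups,
        contact_spheres,
        actuators,
        markers=(),
        gravity=GRAVITY,
        symmetric=True,
        leg_landmarks=None,
        name="model",
    ):
        self.name = name
        self.segments = list(segments)
        self.coords = list(coordinates)
        self.muscles = list(muscles)
        self.muscle_groups = {g.gid: g for g in muscle_groups}
        self.contact_spheres = list(contact_spheres)
        self.actuators = list(actuators)
        self.markers = list(markers)
        self.gravity = float(gravity)
        self.symmetric = bool(symmetric)
        self.leg_landmarks = leg_landmarks or LegLandmarks()

        self.coord_names = [c.name for c in self.coords]
        self.coord_index = {n: i for i, n in enumerate(self.coord_names)}
        self.muscle_names = [m.name for m in self.muscles]
        self.muscle_index = {n: i for i, n in enumerate(self.muscle_names)}
        self.actuator_names = [a.name for a in self.actuators]
        self.segment_names = [s.name for s in self.segments]
        self.segment_index = {n: i for i, n in enumerate(self.segment_names)}

        self.n_q = len(self.coords)
        self.n_mus = len(self.muscles)
        self.n_act = len(self.actuators)

        self._validate()
        self._build_topology()
        self._build_muscle_arrays()
        self._build_mirror_map()

    # ------------------------------------------------------------------ setup
    @property
    def total_mass(self):
        return sum(s.mass for s in self.segments)

    @property
    def pelvis_base_dofs(self):
        return list(self.segments[0].coordinates)

    @property
    def joints(self):
        """(name, coordinate list, coordinate ranges) per joint."""
        out = []
        for s in self.segments:
            if s.coordinates:
                rngs = [self.coords[self.coord_index[c]].range for c in s.coordinates]
                out.append((f"{s.parent}_{s.name}", list(s.coordinates), rngs))
        return out

    def _validate(self):
        seen = {}
        for gid, g in self.muscle_groups.items():
            for m in g.members:
                if m not in self.muscle_index:
                    raise ValueError(f"group {gid}: unknown muscle {m!r}")
                if m in seen:
                    raise ValueError(f"muscle {m!r} in groups {seen[m]!r} and {gid!r}")
                seen[m] = gid
        for m in self.muscle_names:
            if m not in seen:
                raise ValueError(f"muscle {m!r} belongs to no group")
        for a in self.actuators:
            if a.target_coordinate not in self.coord_index:
                raise ValueError(f"actuator targets unknown coordinate {a.target_coordinate!r}")
        for sp in self.contact_spheres:
            if sp.parent_segment not in self.segment_index:
                raise ValueError(f"contact sphere on unknown segment {sp.parent_segment!r}")
        for mk in self.markers:
            if mk.segment not in self.segment_index:
                raise ValueError(f"marker {mk.name!r} on unknown segment {mk.segment!r}")
        if self.symmetric:
            self._check_symmetry()

    def _check_symmetry(self):
        by_name = {s.name: s for s in self.segments}
        for s in self.segments:
            if s.name.endswith("_l"):
                twin = by_name.get(s.name[:-2] + "_r")
                if twin is None or not np.isclose(twin.mass, s.mass) or not np.isclose(
                    twin.inertia, s.inertia
                ):
                    raise ValueError(
                        f"symmetric model: segment {s.name!r} lacks a matching right twin"
                    )

    def _build_topology(self):
        # Topological order check + parent indices.
        self.parent_index = []
        placed = {"ground": -1}
        for i, s in enumerate(self.segments):
            if s.parent not in placed and s.parent not in self.segment_index:
                raise ValueError(f"segment {s.name}: unknown parent {s.parent!r}")
            if s.parent == "ground":
                self.parent_index.append(-1)
            else:
                pi = self.segment_index[s.parent]
                if pi >= i:
                    raise ValueError("segments must be listed parents-first")
                self.parent_index.append(pi)
            placed[s.name] = i
        roots = [i for i, p in enumerate(self.parent_index) if p == -1]
        for i, s in enumerate(self.segments):
            for cname in s.coordinates:
                kind = self.coords[self.coord_index[cname]].kind
                if kind in ("tx", "ty") and self.parent_index[i] != -1:
                    raise ValueError(
                        f"segment {s.name}: translational coordinate {cname} only allowed at root"
                    )
        # Per-coordinate: owning body and kind.
        self.coord_body = np.full(self.n_q, -1, dtype=int)
        self.coord_kind = []
        for i, s in enumerate(self.segments):
            for cname in s.coordinates:
                ci = self.coord_index[cname]
                self.coord_body[ci] = i
                self.coord_kind.append(None)
        self.coord_kind = [c.kind for c in self.coords]
        if np.any(self.coord_body < 0):
            missing = [self.coord_names[i] for i in np.where(self.coord_body < 0)[0]]
            raise ValueError(f"coordinates not attached to any segment: {missing}")
        # Subtree masks: subtree[i, b] True if coordinate i moves body b.
        nb = len(self.segments)
        descend = np.zeros((nb, nb), dtype=bool)
        for b in range(nb):
            a = b
            while a != -1:
                descend[a, b] = True
                a = self.parent_index[a]
        self.subtree = np.zeros((self.n_q, nb), dtype=bool)
        for ci in range(self.n_q):
            self.subtree[ci] = descend[self.coord_body[ci]]
        # Sphere bookkeeping: parent body index and foot side ("left"/"right").
        self.sphere_body = np.array(
            [self.segment_index[sp.parent_segment] for sp in self.contact_spheres], dtype=int
        )
        self.sphere_side = [
            "left" if sp.parent_segment.endswith("_l") else
            "right" if sp.parent_segment.endswith("_r") else "center"
            for sp in self.contact_spheres
        ]
        self.foot_sides = sorted({s for s in self.sphere_side if s != "center"})

    def _build_muscle_arrays(self):
        m = self.n_mus
        self.moment_arm_matrix = np.zeros((m, self.n_q))  # r[mus, coord]
        for k, mus in enumerate(self.muscles):
            for cname, r in mus.moment_arms.items():
                if cname not in self.coord_index:
                    raise ValueError(f"muscle {mus.name}: unknown coordinate {cname!r}")
                self.moment_arm_matrix[k, self.coord_index[cname]] = r
        self._mus_fmax = np.array([mu.max_isometric_force for mu in self.muscles])
        self._mus_lopt = np.array([mu.optimal_fiber_length for mu in self.muscles])
        self._mus_lts = np.array([mu.tendon_slack_length for mu in self.muscles])
        self._mus_cosp = np.cos(np.array([mu.pennation for mu in self.muscles]))
        self._mus_lref = np.array([mu.reference_length for mu in self.muscles])
        self._mus_vmax = np.array([mu.max_contraction_velocity for mu in self.muscles])
        self._mus_tact = np.array([mu.activation_time_constant for mu in self.muscles])
        self._mus_tdeact = np.array([mu.deactivation_time_constant for mu in self.muscles])
        self._act_coord = np.array(
            [self.coord_index[a.target_coordinate] for a in self.actuators], dtype=int
        )
        self._act_mag = np.array([a.max_magnitude for a in self.actuators])

    def _build_mirror_map(self):
        """Left/right coordinate, muscle and actuator exchange, by _l/_r naming."""

        def pair(names):
            perm = list(range(len(names)))
            idx = {n: i for i, n in enumerate(names)}
            for i, n in enumerate(names):
                if n.endswith("_l") and (n[:-2] + "_r") in idx:
                    perm[i] = idx[n[:-2] + "_r"]
                elif n.endswith("_r") and (n[:-2] + "_l") in idx:
                    perm[i] = idx[n[:-2] + "_l"]
                elif "_l_" in n and n.replace("_l_", "_r_") in idx:
                    perm[i] = idx[n.replace("_l_", "_r_")]
                elif "_r_" in n and n.replace("_r_", "_l_") in idx:
                    perm[i] = idx[n.replace("_r_", "_l_")]
            return np.array(perm, dtype=int)

        self.coord_mirror = pair(self.coord_names)
        self.muscle_mirror = pair(self.muscle_names)
        self.actuator_mirror = pair(self.actuator_names)

    # ------------------------------------------------------------- kinematics
    def _fk(self, Q, U=None, Udot=None):
        """Batched forward kinematics.

        Q, U, Udot: (B, n_q).  Returns a workspace dict with per-body frame
        origin/orientation, COM position/velocity, bias COM acceleration (the
        acceleration with Udot = 0), and per-coordinate rotation pivots.
        """
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        B = Q.shape[0]
        nb = len(self.segments)
        vel = U is not None
        U = np.atleast_2d(U) if vel else np.zeros_like(Q)

        theta = np.zeros((B, nb))
        omega = np.zeros((B, nb))
        origin = np.zeros((B, nb, 2))
        ovel = np.zeros((B, nb, 2))
        obias = np.zeros((B, nb, 2))  # origin acceleration with Udot = 0
        com = np.zeros((B, nb, 2))
        cvel = np.zeros((B, nb, 2))
        cbias = np.zeros((B, nb, 2))

        def rot(th, v):
            c, s = np.cos(th), np.sin(th)
            return np.stack([c * v[0] - s * v[1], s * v[0] + c * v[1]], axis=-1)

        def zcross(w, v):  # w scalar(B,), v (B,2) -> w * zhat x v
            return np.stack([-w * v[..., 1], w * v[..., 0]], axis=-1)

        for b, seg in enumerate(self.segments):
            p = self.parent_index[b]
            if p == -1:
                th_p = np.zeros(B)
                om_p = np.zeros(B)
                o_p = np.zeros((B, 2))
                v_p = np.zeros((B, 2))
                a_p = np.zeros((B, 2))
            else:
                th_p, om_p = theta[:, p], omega[:, p]
                o_p, v_p, a_p = origin[:, p], ovel[:, p], obias[:, p]
            off = rot(th_p, np.asarray(seg.parent_offset, dtype=float))
            anchor = o_p + off
            anchor_v = v_p + zcross(om_p, off)
            anchor_a = a_p + zcross(np.zeros(B), off) - om_p[:, None] ** 2 * off

            th_b, om_b = th_p.copy(), om_p.copy()
            o_b, v_b, a_b = anchor, anchor_v, anchor_a
            for cname in seg.coordinates:
                ci = self.coord_index[cname]
                kind = self.coord_kind[ci]
                if kind == "tx":
                    o_b = o_b + np.stack([Q[:, ci], np.zeros(B)], axis=-1)
                    v_b = v_b + np.stack([U[:, ci], np.zeros(B)], axis=-1)
                elif kind == "ty":
                    o_b = o_b + np.stack([np.zeros(B), Q[:, ci]], axis=-1)
                    v_b = v_b + np.stack([np.zeros(B), U[:, ci]], axis=-1)
                else:  # rz
                    th_b = th_b + Q[:, ci]
                    om_b = om_b + U[:, ci]
            theta[:, b], omega[:, b] = th_b, om_b
            origin[:, b], ovel[:, b], obias[:, b] = o_b, v_b, a_b

            co = rot(th_b, np.asarray(seg.com_offset, dtype=float))
            com[:, b] = o_b + co
            cvel[:, b] = v_b + zcross(om_b, co)
            cbias[:, b] = a_b - om_b[:, None] ** 2 * co

        # Rotation pivots per coordinate: world position of the owning body's
        # frame origin (rotation is applied about the body origin).
        pivot = np.zeros((B, self.n_q, 2))
        for ci in range(self.n_q):
            pivot[:, ci] = origin[:, self.coord_body[ci]]

        # Geometric Jacobian of each body's COM wrt each coordinate, (B,nb,nq,2),
        # and the rotation-share mask (nb, nq).
        J = np.zeros((B, nb, self.n_q, 2))
        rotmask = np.zeros((nb, self.n_q))
        for ci in range(self.n_q):
            kind = self.coord_kind[ci]
            for b in range(nb):
                if not self.subtree[ci, b]:
                    continue
                if kind == "tx":
                    J[:, b, ci, 0] = 1.0
                elif kind == "ty":
                    J[:, b, ci, 1] = 1.0
                else:
                    r = com[:, b] - pivot[:, ci]
                    J[:, b, ci, 0] = -r[:, 1]
                    J[:, b, ci, 1] = r[:, 0]
                    rotmask[b, ci] = 1.0

        return {
            "B": B, "theta": theta, "omega": omega, "origin": origin,
            "ovel": ovel, "com": com, "cvel": cvel, "cbias": cbias,
            "pivot": pivot, "J": J, "rotmask": rotmask,
        }

    def point_kinematics(self, ws, segment, offset):
        """World position/velocity of a point fixed on a segment, from a
        workspace returned by _fk."""
        b = self.segment_index[segment]
        th = ws["theta"][:, b]
        c, s = np.cos(th), np.sin(th)
        ox, oy = float(offset[0]), float(offset[1])
        local = np.stack([c * ox - s * oy, s * ox + c * oy], axis=-1)
        pos = ws["origin"][:, b] + local
        om = ws["omega"][:, b]
        vel = ws["ovel"][:, b] + np.stack([-om * local[:, 1], om * local[:, 0]], axis=-1)
        return pos, vel

    def _point_jacobian_apply(self, ws, body, point, F, tau):
        """Accumulate generalized forces of force F (B,2) applied at world
        point (B,2) on body into tau (B, n_q)."""
        for ci in range(self.n_q):
            if not self.subtree[ci, body]:
                continue
            kind = self.coord_kind[ci]
            if kind == "tx":
                tau[:, ci] += F[:, 0]
            elif kind == "ty":
                tau[:, ci] += F[:, 1]
            else:
                r = point - ws["pivot"][:, ci]
                tau[:, ci] += r[:, 0] * F[:, 1] - r[:, 1] * F[:, 0]

    # --------------------------------------------------------------- dynamics
    def mass_matrix(self, ws):
        """(B, n_q, n_q) joint-space inertia matrix."""
        masses = np.array([s.mass for s in self.segments])
        inertias = np.array([s.inertia for s in self.segments])
        J = ws["J"]
        M = np.einsum("bnid,bnjd,n->bij", J, J, masses)
        M += np.einsum("ni,nj,n->ij", ws["rotmask"], ws["rotmask"], inertias)[None]
        return M

    def bias_forces(self, ws, gravity=True):
        """(B, n_q) velocity-product + gravity generalized forces: the
        torques/forces required to sustain Udot = 0."""
        masses = np.array([s.mass for s in self.segments])
        g = np.array([0.0, -self.gravity if gravity else 0.0])
        w = masses[None, :, None] * (ws["cbias"] - g[None, None, :])  # (B,nb,2)
        return np.einsum("bnid,bnd->bi", ws["J"], w)

    def inverse_dynamics(self, Q, U, Udot, gravity=True):
        """Generalized forces M(q)udot + c(q,u) + g(q), batched."""
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        U = np.atleast_2d(np.asarray(U, dtype=float))
        Udot = np.atleast_2d(np.asarray(Udot, dtype=float))
        ws = self._fk(Q, U)
        tau = np.einsum("bij,bj->bi", self.mass_matrix(ws), Udot)
        tau += self.bias_forces(ws, gravity=gravity)
        return tau

    def muscle_lengths(self, Q, U=None):
        """Musculotendon lengths (B, n_mus) and, if U given, velocities."""
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        lmt = self._mus_lref[None, :] - Q @ self.moment_arm_matrix.T
        if U is None:
            return lmt
        vmt = -np.atleast_2d(np.asarray(U, dtype=float)) @ self.moment_arm_matrix.T
        return lmt, vmt

    def muscle_forces(self, Q, U, A, active=None):
        """Tensile muscle forces (B, n_mus); inactive muscles produce zero
        (their passive properties are taken as negligible, matching the
        reduced-muscle-set modeling assumption)."""
        lmt, vmt = self.muscle_lengths(Q, np.atleast_2d(U))
        cosp = self._mus_cosp[None, :]
        fiber = (lmt - self._mus_lts[None, :]) / cosp
        floor = 0.1 * self._mus_lopt[None, :]
        eps = 0.05 * self._mus_lopt[None, :]
        sh = fiber - floor
        fiber = floor + 0.5 * (sh + np.sqrt(sh * sh + eps * eps))
        lnorm = fiber / self._mus_lopt[None, :]
        vnorm = vmt / (cosp * self._mus_lopt[None, :] * self._mus_vmax[None, :])
        mult = (
            np.atleast_2d(A) * active_force_length(lnorm) * force_velocity(vnorm)
            + passive_force_length(lnorm)
        )
        F = self._mus_fmax[None, :] * mult * cosp
        if active is not None:
            F = F * np.asarray(active, dtype=float)[None, :]
        return F

    def contact_forces(self, ws):
        """Per-sphere ground forces.  Returns (force (B,ns,2), point (B,ns,2))
        with force = (tangential_x, normal_y) in world frame."""
        B = ws["B"]
        ns = len(self.contact_spheres)
        F = np.zeros((B, ns, 2))
        P = np.zeros((B, ns, 2))
        for k, sp in enumerate(self.contact_spheres):
            b = self.sphere_body[k]
            pos, vel = self.point_kinematics(ws, sp.parent_segment, sp.offset)
            om = ws["omega"][:, b]
            penetration = sp.radius - pos[:, 1]
            pen_rate = -vel[:, 1]
            slip = vel[:, 0] + om * sp.radius
            ft, fn = contact_force(penetration, pen_rate, slip, sp)
            F[:, k, 0], F[:, k, 1] = ft, fn
            P[:, k, 0], P[:, k, 1] = pos[:, 0], pos[:, 1] - sp.radius
        return F, P

    def foot_contact_totals(self, Q, U):
        """Vector-summed contact force per foot side: {side: (B, 2)}."""
        ws = self._fk(np.atleast_2d(Q), np.atleast_2d(U))
        F, _ = self.contact_forces(ws)
        out = {}
        for side in self.foot_sides:
            mask = np.array([s == side for s in self.sphere_side])
            out[side] = F[:, mask, :].sum(axis=1)
        return out

    def applied_forces(self, ws, Q, U, A, excitation, actuator_controls,
                       active_muscles=None):
        """Generalized applied forces (B, n_q): muscles + contact + actuators.

        actuator_controls are dimensionless in [-1, 1], scaled by each
        actuator's max magnitude.  Returns (tau, per-foot contact totals).
        """
        B = ws["B"]
        tau = np.zeros((B, self.n_q))
        # Muscles.
        Fm = self.muscle_forces(Q, U, A, active=active_muscles)
        tau += Fm @ self.moment_arm_matrix
        # Contact.
        Fc, Pc = self.contact_forces(ws)
        for k in range(len(self.contact_spheres)):
            self._point_jacobian_apply(ws, self.sphere_body[k], Pc[:, k], Fc[:, k], tau)
        foot = {}
        for side in self.foot_sides:
            mask = np.array([s == side for s in self.sphere_side])
            foot[side] = Fc[:, mask, :].sum(axis=1)
        # Actuators.
        R = np.atleast_2d(actuator_controls)
        scaled = R * self._act_mag[None, :]
        np.add.at(tau.T, self._act_coord, scaled.T)
        return tau, foot

    def forward_dynamics(self, Q, U, A, excitation, actuator_controls,
                         active_muscles=None, return_extras=False):
        """Explicit dynamics: coordinate accelerations Udot (B, n_q) and
        activation rates Adot (B, n_mus)."""
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        U = np.atleast_2d(np.asarray(U, dtype=float))
        A = np.atleast_2d(np.asarray(A, dtype=float))
        E = np.atleast_2d(np.asarray(excitation, dtype=float))
        ws = self._fk(Q, U)
        M = self.mass_matrix(ws)
        bias = self.bias_forces(ws)
        tau, foot = self.applied_forces(ws, Q, U, A, E, actuator_controls,
                                        active_muscles=active_muscles)
        try:
            Udot = np.linalg.solve(M, (tau - bias)[..., None])[..., 0]
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                f"singular mass matrix for configuration q={Q[0]}"
            ) from err
        Adot = _activation_rate(E, A, self._mus_tact[None, :], self._mus_tdeact[None, :])
        if active_muscles is not None:
            Adot = Adot * np.asarray(active_muscles, dtype=float)[None, :]
        if return_extras:
            return Udot, Adot, {"ws": ws, "foot": foot, "tau": tau, "bias": bias, "M": M}
        return Udot, Adot

    def marker_positions(self, Q, markers=None):
        """World positions of markers, (B, n_markers, 2)."""
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        ws = self._fk(Q)
        markers = self.markers if markers is None else markers
        out = np.zeros((Q.shape[0], len(markers), 2))
        for k, mk in enumerate(markers):
            out[:, k], _ = self.point_kinematics(ws, mk.segment, mk.offset)
        return out

    def com_position(self, Q):
        """Whole-body center of mass, (B, 2)."""
        ws = self._fk(np.atleast_2d(np.asarray(Q, dtype=float)))
        masses = np.array([s.mass for s in self.segments])
        return (ws["com"] * masses[None, :, None]).sum(axis=1) / masses.sum()

    def leg_landmark_points(self, Q):
        """(left point (B,2), right point (B,2)) for the clearance constraint,
        plus their fixed lateral offsets."""
        ws = self._fk(np.atleast_2d(np.asarray(Q, dtype=float)))
        lm = self.leg_landmarks
        pl, _ = self.point_kinematics(ws, lm.left_segment, lm.left_offset)
        pr, _ = self.point_kinematics(ws, lm.right_segment, lm.right_offset)
        return pl, pr, lm.left_lateral, lm.right_lateral

    def mirror_state(self, q, u=None, a=None):
        """Left/right exchange of a state (planar sagittal mirror)."""
        q = np.asarray(q, dtype=float)
        out = [q[..., self.coord_mirror]]
        if u is not None:
            out.append(np.asarray(u, dtype=float)[..., self.coord_mirror])
        if a is not None:
            out.append(np.asarray(a, dtype=float)[..., self.muscle_mirror])
        return out[0] if len(out) == 1 else tuple(out)


def dynamics_residual(state, state_derivative, controls, model, active_muscles=None):
    """Implicit dynamics residual; zero iff the triplet satisfies the
    multibody + muscle + contact equations.

    state = (q, u, a); state_derivative = (qdot, udot, adot);
    controls = (excitation, actuator_controls).  All batched (B, .) or flat.
    Returns (B, n_q + n_q + n_mus) residual [qdot - u; ID - applied; adot - f_a].
    """
    q, u, a = (np.atleast_2d(np.asarray(x, dtype=float)) for x in state)
    qdot, udot, adot = (np.atleast_2d(np.asarray(x, dtype=float)) for x in state_derivative)
    e, r = (np.atleast_2d(np.asarray(x, dtype=float)) for x in controls)
    for name, arr in (("state", q), ("state_derivative", udot), ("controls", e)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"dynamics_residual: non-finite {name}")
    ws = model._fk(q, u)
    M = model.mass_matrix(ws)
    bias = model.bias_forces(ws)
    tau, _ = model.applied_forces(ws, q, u, a, e, r, active_muscles=active_muscles)
    res_q = qdot - u
    res_u = np.einsum("bij,bj->bi", M, udot) + bias - tau
    adot_model = _activation_rate(e, a, model._mus_tact[None, :], model._mus_tdeact[None, :])
    if active_muscles is not None:
        adot_model = adot_model * np.asarray(active_muscles, dtype=float)[None, :]
    res_a = adot - adot_model
    return np.concatenate([res_q, res_u, res_a], axis=1)


def percent_body_weight(force, total_mass, gravity=GRAVITY):
    """Express a force (N) as percent of body weight for a given mass (kg)."""
    return 100.0 * abs(float(force)) / (float(total_mass) * gravity)


# --------------------------------------------------------------- fixtures ---
def planar_biped(total_mass=76.2, vasti_elements=2):
    """Default planar biped fixture (sagittal plane, 10 coordinates).

    Segment masses follow standard anthropometric fractions of the given
    total mass, with head/arms/trunk lumped into one trunk segment whose
    pitch actuator stands in for volitional trunk and arm effort.
    """
    mt = float(total_mass)
    m_pelvis = 0.142 * mt
    m_thigh = 0.100 * mt
    m_shank = 0.0465 * mt
    m_foot = 0.0145 * mt
    m_trunk = mt - m_pelvis - 2 * (m_thigh + m_shank + m_foot)

    L_thigh, L_shank, L_trunk = 0.45, 0.43, 0.80

    coords = [
        Coordinate("pelvis_tx", "tx", (-1.0, 1.0), (-2.0, 2.0)),
        Coordinate("pelvis_ty", "ty", (0.55, 1.35), (-2.0, 2.0)),
        Coordinate("pelvis_rot", "rz", (-0.6, 0.6), (-6.0, 6.0)),
        Coordinate("trunk_pitch", "rz", (-0.6, 0.6), (-6.0, 6.0)),
        Coordinate("hip_l", "rz", (-0.6, 1.2), (-8.0, 8.0)),
        Coordinate("knee_l", "rz", (-0.05, 1.2), (-8.0, 8.0)),
        Coordinate("ankle_l", "rz", (-0.7, 0.7), (-8.0, 8.0)),
        Coordinate("hip_r", "rz", (-0.6, 1.2), (-8.0, 8.0)),
        Coordinate("knee_r", "rz", (-0.05, 1.2), (-8.0, 8.0)),
        Coordinate("ankle_r", "rz", (-0.7, 0.7), (-8.0, 8.0)),
    ]

    def leg(side):
        s = side[0]  # 'l' / 'r'
        return [
            Segment(f"thigh_{s}", m_thigh, m_thigh * L_thigh**2 / 12, L_thigh,
                    parent="pelvis", parent_offset=(0.0, 0.0),
                    com_offset=(0.0, -0.433 * L_thigh), coordinates=(f"hip_{s}",)),
            Segment(f"shank_{s}", m_shank, m_shank * L_shank**2 / 12, L_shank,
                    parent=f"thigh_{s}", parent_offset=(0.0, -L_thigh),
                    com_offset=(0.0, -0.433 * L_shank), coordinates=(f"knee_{s}",)),
            Segment(f"foot_{s}", m_foot, 0.0050, 0.25,
                    parent=f"shank_{s}", parent_offset=(0.0, -L_shank),
                    com_offset=(0.05, -0.04), coordinates=(f"ankle_{s}",)),
        ]

    segments = [
        Segment("pelvis", m_pelvis, 0.08, 0.15, parent="ground",
                com_offset=(-0.02, 0.02),
                coordinates=("pelvis_tx", "pelvis_ty", "pelvis_rot")),
        Segment("trunk", m_trunk, m_trunk * L_trunk**2 / 12, L_trunk,
                parent="pelvis", parent_offset=(0.0, 0.08),
                com_offset=(0.0, 0.35), coordinates=("trunk_pitch",)),
        *leg("left"),
        *leg("right"),
    ]

    # Knee flexion is positive with the shank rotating rearward, so the knee
    # coordinate enters the shank rotation with negative sign; that sign is
    # carried by the moment arms instead, so here knee_x rotates the shank
    # directly and extensors get negative arms.
    def muscles_for(side):
        s = side[0]
        out = [
            MuscleTendonUnit(f"iliopsoas_{s}", 1500.0, 0.12, 0.10,
                             moment_arms={f"hip_{s}": 0.040}, group_id=f"iliopsoas_{s}",
                             side=side),
            MuscleTendonUnit(f"tib_ant_{s}", 1200.0, 0.07, 0.22,
                             moment_arms={f"ankle_{s}": 0.035}, group_id=f"ta_{s}",
                             side=side),
        ]
        if vasti_elements == 1:
            out.append(
                MuscleTendonUnit(f"vasti_{s}", 5000.0, 0.09, 0.13,
                                 moment_arms={f"knee_{s}": -0.045},
                                 group_id=f"vasti_{s}", side=side)
            )
        else:
            for el in ("med", "lat")[:vasti_elements]:
                out.append(
                    MuscleTendonUnit(f"vasti_{el}_{s}", 5000.0 / vasti_elements, 0.09, 0.13,
                                     moment_arms={f"knee_{s}": -0.045},
                                     group_id=f"vasti_{s}", side=side)
                )
        return out

    muscles = muscles_for("left") + muscles_for("right") + [
        MuscleTendonUnit("sartorius_r", 250.0, 0.40, 0.10,
                         moment_arms={"hip_r": 0.035, "knee_r": 0.020},
                         group_id="sartorius_r", side="right"),
        MuscleTendonUnit("bfsh_r", 800.0, 0.12, 0.09,
                         moment_arms={"knee_r": 0.025}, group_id="bfsh_r", side="right"),
        MuscleTendonUnit("tfl_l", 400.0, 0.10, 0.40,
                         moment_arms={"hip_l": 0.030}, group_id="tfl_l", side="left"),
    ]

    def group_members(gid):
        return tuple(m.name for m in muscles if m.group_id == gid)

    groups = [
        MuscleGroup("iliopsoas_l", group_members("iliopsoas_l"), "left", "implanted"),
        MuscleGroup("iliopsoas_r", group_members("iliopsoas_r"), "right", "surface"),
        MuscleGroup("vasti_l", group_members("vasti_l"), "left", "implanted"),
        MuscleGroup("vasti_r", group_members("vasti_r"), "right", "implanted"),
        MuscleGroup("ta_l", group_members("ta_l"), "left", "implanted"),
        MuscleGroup("ta_r", group_members("ta_r"), "right", "implanted"),
        MuscleGroup("sartorius_r", ("sartorius_r",), "right", "surface"),
        MuscleGroup("bfsh_r", ("bfsh_r",), "right", "surface"),
        MuscleGroup("tfl_l", ("tfl_l",), "left", "implanted"),
    ]

    def foot_spheres(side):
        s = side[0]
        geom = [("heel", (-0.06, -0.05)), ("met", (0.10, -0.055)), ("toe", (0.16, -0.05))]
        return [ContactSphere(f"foot_{s}", off, 0.02) for _, off in geom]

    spheres = foot_spheres("left") + foot_spheres("right")

    actuators = [
        ReserveActuator("pelvis_tx", "force", 250.0, "penalized"),
        ReserveActuator("pelvis_ty", "force", 500.0, "penalized"),
        ReserveActuator("pelvis_rot", "torque", 150.0, "penalized"),
        ReserveActuator("trunk_pitch", "torque", 150.0, "normal"),
        ReserveActuator("hip_l", "torque", 80.0, "penalized"),
        ReserveActuator("knee_l", "torque", 80.0, "penalized"),
        ReserveActuator("ankle_l", "torque", 40.0, "penalized"),
        ReserveActuator("hip_r", "torque", 80.0, "penalized"),
        ReserveActuator("knee_r", "torque", 80.0, "penalized"),
        ReserveActuator("ankle_r", "torque", 40.0, "penalized"),
    ]

    markers = [
        Marker("SACR", "pelvis", (-0.08, 0.05), bony_prominence=True),
        Marker("C7", "trunk", (-0.02, 0.62), bony_prominence=True),
        Marker("KNEE_L", "thigh_l", (0.0, -L_thigh), bony_prominence=True),
        Marker("KNEE_R", "thigh_r", (0.0, -L_thigh), bony_prominence=True),
        Marker("ANK_L", "shank_l", (0.0, -L_shank), bony_prominence=True),
        Marker("ANK_R", "shank_r", (0.0, -L_shank), bony_prominence=True),
        Marker("HEEL_L", "foot_l", (-0.06, -0.04)),
        Marker("HEEL_R", "foot_r", (-0.06, -0.04)),
        Marker("TOE_L", "foot_l", (0.16, -0.04)),
        Marker("TOE_R", "foot_r", (0.16, -0.04)),
    ]
    for mk in markers:
        if mk.bony_prominence:
            mk.weight = 10.0

    landmarks = LegLandmarks("shank_l", (0.0, -0.2), 0.10, "shank_r", (0.0, -0.2), -0.10)

    return MskModel(
        segments, coords, muscles, groups, spheres, actuators, markers,
        gravity=GRAVITY, symmetric=True, leg_landmarks=landmarks,
        name="planar_biped",
    )


def pendulum_model(mass=1.0, length=1.0, inertia=None, torque_max=20.0):
    """Single passive pendulum pinned to ground; used as a dynamics oracle."""
    if inertia is None:
        inertia = 0.0  # point mass at the tip
    coords = [Coordinate("theta", "rz", (-2 * np.pi, 2 * np.pi), (-50.0, 50.0))]
    seg = Segment("rod", mass, inertia, length, parent="ground",
                  com_offset=(0.0, -length), coordinates=("theta",))
    mus = MuscleTendonUnit("dummy", 1.0, 0.1, 0.1, moment_arms={}, group_id="dummy")
    grp = MuscleGroup("dummy", ("dummy",), "left")
    act = ReserveActuator("theta", "torque", torque_max, "normal")
    return MskModel([seg], coords, [mus], [grp], [], [act], markers=(),
                    symmetric=False, name="pendulum")


# ----------------------------------------------------------------- config ---
def _pyfloat(x):
    if isinstance(x, (list, tuple)):
        return [float(v) for v in x]
    return float(x)


def _model_to_dict(model):
    return _scrub({
        "name": model.name,
        "gravity": model.gravity,
        "symmetric": model.symmetric,
        "coordinates": [
            {"name": c.name, "kind": c.kind, "range": list(c.range),
             "default_speed_range": list(c.default_speed_range)}
            for c in model.coords
        ],
        "segments": [
            {"name": s.name, "mass": s.mass, "inertia": s.inertia, "length": s.length,
             "parent": s.parent, "parent_offset": list(s.parent_offset),
             "com_offset": list(s.com_offset), "coordinates": list(s.coordinates)}
            for s in model.segments
        ],
        "muscles": [
            {"name": m.name, "max_isometric_force": m.max_isometric_force,
             "optimal_fiber_length": m.optimal_fiber_length,
             "tendon_slack_length": m.tendon_slack_length, "pennation": m.pennation,
             "activation_time_constant": m.activation_time_constant,
             "deactivation_time_constant": m.deactivation_time_constant,
             "moment_arms": dict(m.moment_arms), "reference_length": m.reference_length,
             "group_id": m.group_id, "side": m.side}
            for m in model.muscles
        ],
        "muscle_groups": [
            {"gid": g.gid, "members": list(g.members), "side": g.side, "method": g.method}
            for g in model.muscle_groups.values()
        ],
        "contact_spheres": [
            {"parent_segment": sp.parent_segment, "offset": list(sp.offset),
             "radius": sp.radius, "stiffness": sp.stiffness,
             "dissipation": sp.dissipation, "exponent": sp.exponent,
             "mu_static": sp.mu_static, "mu_dynamic": sp.mu_dynamic,
             "mu_viscous": sp.mu_viscous, "smoothing": sp.smoothing,
             "transition_velocity": sp.transition_velocity}
            for sp in model.contact_spheres
        ],
        "actuators": [
            {"target_coordinate": a.target_coordinate, "kind": a.kind,
             "max_magnitude": a.max_magnitude, "cost_weight_tag": a.cost_weight_tag,
             "name": a.name}
            for a in model.actuators
        ],
        "markers": [
            {"name": mk.name, "segment": mk.segment, "offset": list(mk.offset),
             "weight": mk.weight, "bony_prominence": mk.bony_prominence}
            for mk in model.markers
        ],
        "leg_landmarks": {
            "left_segment": model.leg_landmarks.left_segment,
            "left_offset": list(model.leg_landmarks.left_offset),
            "left_lateral": model.leg_landmarks.left_lateral,
            "right_segment": model.leg_landmarks.right_segment,
            "right_offset": list(model.leg_landmarks.right_offset),
            "right_lateral": model.leg_landmarks.right_lateral,
        },
    })


def _scrub(obj):
    """Recursively convert numpy scalars/sequences to plain python types."""
    if isinstance(obj, dict):
        return {k: _scrub(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_scrub(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _model_from_dict(d):
    coords = [Coordinate(c["name"], c["kind"], tuple(c["range"]),
                         tuple(c.get("default_speed_range", (-20.0, 20.0))))
              for c in d["coordinates"]]
    segs = [Segment(s["name"], s["mass"], s["inertia"], s["length"], s["parent"],
                    tuple(s.get("parent_offset", (0.0, 0.0))),
                    tuple(s.get("com_offset", (0.0, 0.0))),
                    tuple(s.get("coordinates", ())))
            for s in d["segments"]]
    mus = [MuscleTendonUnit(m["name"], m["max_isometric_force"], m["optimal_fiber_length"],
                            m["tendon_slack_length"], m.get("pennation", 0.0),
                            m.get("activation_time_constant", 0.015),
                            m.get("deactivation_time_constant", 0.060),
                            dict(m.get("moment_arms", {})), m.get("reference_length"),
                            m.get("group_id", ""), m.get("side", ""))
           for m in d["muscles"]]
    groups = [MuscleGroup(g["gid"], tuple(g["members"]), g["side"],
                          g.get("method", "implanted"))
              for g in d["muscle_groups"]]
    spheres = [ContactSphere(sp["parent_segment"], tuple(sp["offset"]), sp["radius"],
                             sp.get("stiffness", 1.0e6), sp.get("dissipation", 2.0),
                             sp.get("exponent", 1.5), sp.get("mu_static", 0.8),
                             sp.get("mu_dynamic", 0.8), sp.get("mu_viscous", 0.5),
                             sp.get("smoothing", 1.0e-4),
                             sp.get("transition_velocity", 0.05))
               for sp in d["contact_spheres"]]
    acts = [ReserveActuator(a["target_coordinate"], a["kind"], a["max_magnitude"],
                            a.get("cost_weight_tag", "penalized"), a.get("name", ""))
            for a in d["actuators"]]
    marks = [Marker(mk["name"], mk["segment"], tuple(mk["offset"]),
                    mk.get("weight", 1.0), mk.get("bony_prominence", False))
             for mk in d.get("markers", [])]
    lm = d.get("leg_landmarks")
    landmarks = LegLandmarks(**{**lm, "left_offset": tuple(lm["left_offset"]),
                                "right_offset": tuple(lm["right_offset"])}) if lm else None
    return MskModel(segs, coords, mus, groups, spheres, acts, marks,
                    gravity=d.get("gravity", GRAVITY),
                    symmetric=d.get("symmetric", True),
                    leg_landmarks=landmarks, name=d.get("name", "model"))


def save_model(model, path):
    with open(path, "w") as fh:
        yaml.safe_dump(_model_to_dict(model), fh, sort_keys=False)


def load_model(path):
    with open(path) as fh:
        return _model_from_dict(yaml.safe_load(fh))
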