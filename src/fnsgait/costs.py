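"""Cost subterms for the optimal-control problems.

Six subterms are evaluated on discretized trajectories by trapezoidal
quadrature on the collocation grid:

* marker tracking        J_mt = int sum_k w_k |x_k,model - x_k,meas|^2 dt
* contact tracking       J_ct = 1/(m g) int sum_feet |F_model - F_meas|^2 dt
* muscle-group synergy   J_s  = int sum_groups (e1-e2)^2 [+ (e1-e3)^2] dt
* control effort         J_e  = [1/d] int sum_channels w_k e_k^2 dt
* energy-injection       J_p  = int 10 (e_rect_abd^2 + e_ext_obl^2) dt
* auxiliary derivatives  J_ad = int sum_tendons (dF/dt)^2 dt

The tracking composition weights effort by the CoM travel distance d (so the
1/d inside J_e is omitted); the predictive composition drops both tracking
terms and keeps the 1/d normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerSet",
    "ReferenceData",
    "CostWeights",
    "eval_marker_tracking",
    "eval_contact_tracking",
    "eval_synergy",
    "eval_effort",
    "eval_energy_penalty",
    "eval_aux_deriv",
    "compose_cost",
    "cost_report",
]

BONY_WEIGHT_FACTOR = 10.0


def _trapz_weights(t):
    """Trapezoidal quadrature weights for an arbitrary increasing grid."""
    t = np.asarray(t, dtype=float)
    w = np.zeros_like(t)
    dt = np.diff(t)
    w[:-1] += 0.5 * dt
    w[1:] += 0.5 * dt
    return w


def _integrate(values, t):
    """Trapezoidal integral of per-node scalar values."""
    return float(_trapz_weights(t) @ np.asarray(values, dtype=float))


@dataclass
class MarkerSet:
    """Tracking markers with per-marker weights; markers flagged as bony
    prominences get a ten-fold weight (higher placement accuracy)."""

    markers: list  # of model.Marker

    def __post_init__(self):
        for mk in self.markers:
            if mk.weight <= 0:
                raise ValueError(f"marker {mk.name}: weight must be > 0")

    @classmethod
    def from_model(cls, model, base_weight=1.0):
        out = []
        for mk in model.markers:
            w = base_weight * (BONY_WEIGHT_FACTOR if mk.bony_prominence else 1.0)
            clone = type(mk)(mk.name, mk.segment, mk.offset, w, mk.bony_prominence)
            out.append(clone)
        return cls(out)

    @property
    def names(self):
        return [mk.name for mk in self.markers]

    @property
    def weights(self):
        return np.array([mk.weight for mk in self.markers])


@dataclass
class ReferenceData:
    """Measured (or synthesized) reference: marker trajectories and per-foot
    ground contact forces, each on its own sampling grid."""

    marker_time: np.ndarray  # (nm_t,) s
    marker_names: list
    marker_xy: np.ndarray  # (nm_t, n_markers, 2) m
    force_time: np.ndarray  # (nf_t,) s
    force_sides: list  # e.g. ["left", "right"]
    force_xy: np.ndarray  # (nf_t, n_sides, 2) N
    marker_rate: float = 100.0  # Hz
    force_rate: float = 1000.0  # Hz
    nt_speed_ranges: dict = field(default_factory=dict)  # coord -> (lo, hi)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.marker_time = np.asarray(self.marker_time, dtype=float)
        self.force_time = np.asarray(self.force_time, dtype=float)
        self.marker_xy = np.asarray(self.marker_xy, dtype=float)
        self.force_xy = np.asarray(self.force_xy, dtype=float)
        for label, arr in (("marker", self.marker_xy), ("force", self.force_xy)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"reference {label} data contains non-finite values")

    def _check_span(self, t):
        if t[0] < self.marker_time[0] - 1e-9 or t[-1] > self.marker_time[-1] + 1e-9:
            raise ValueError(
                "reference data do not cover the trajectory time span "
                f"[{t[0]:.4f}, {t[-1]:.4f}]"
            )

    def markers_at(self, t, names):
        """Linear interpolation of the named markers onto grid t: (n, k, 2)."""
        t = np.asarray(t, dtype=float)
        self._check_span(t)
        idx = []
        for nm in names:
            if nm not in self.marker_names:
                raise KeyError(f"marker {nm!r} present in model but absent in reference")
            idx.append(self.marker_names.index(nm))
        out = np.zeros((t.size, len(idx), 2))
        for j, k in enumerate(idx):
            for d in range(2):
                out[:, j, d] = np.interp(t, self.marker_time, self.marker_xy[:, k, d])
        return out

    def forces_at(self, t, sides):
        t = np.asarray(t, dtype=float)
        idx = []
        for s in sides:
            if s not in self.force_sides:
                raise KeyError(f"foot side {s!r} has no reference force trace")
            idx.append(self.force_sides.index(s))
        out = np.zeros((t.size, len(idx), 2))
        for j, k in enumerate(idx):
            for d in range(2):
                out[:, j, d] = np.interp(t, self.force_time, self.force_xy[:, k, d])
        return out


@dataclass
class CostWeights:
    """Subterm weights (all >= 0) and per-channel control weights.  Reserve
    actuators tagged 'penalized' are weighted ``reserve_penalty`` times the
    (equal) muscle weight in the effort subterm."""

    w_mt: float = 1.0
    w_ct: float = 1.0
    w_s: float = 1.0
    w_e: float = 1.0
    w_p: float = 1.0
    w_ad: float = 1.0
    muscle_weight: float = 1.0
    reserve_penalty: float = 10.0

    def __post_init__(self):
        for name in ("w_mt", "w_ct", "w_s", "w_e", "w_p", "w_ad",
                     "muscle_weight", "reserve_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"cost weight {name} must be >= 0")

    def control_weights(self, model, active_actuators=None):
        """(muscle weights (n_mus,), actuator weights (n_act_active,))."""
        wm = np.full(model.n_mus, self.muscle_weight)
        acts = model.actuators if active_actuators is None else [
            a for a in model.actuators if a.name in active_actuators
        ]
        wa = np.array([
            self.muscle_weight * (self.reserve_penalty
                                  if a.cost_weight_tag == "penalized" else 1.0)
            for a in acts
        ])
        return wm, wa


# --------------------------------------------------------------- subterms ---
def eval_marker_tracking(traj, ref, markers, model=None):
    """Marker kinematic tracking cost (m^2 s)."""
    model = model or traj.model
    if model is None:
        raise ValueError("eval_marker_tracking: trajectory carries no model")
    pos = model.marker_positions(traj.q, markers.markers)  # (n, k, 2)
    meas = ref.markers_at(traj.time, markers.names)
    err2 = ((pos - meas) ** 2).sum(axis=2)  # (n, k)
    per_node = err2 @ markers.weights
    return _integrate(per_node, traj.time)


def eval_contact_tracking(traj, ref, model=None):
    """Contact-force tracking cost (dimensionless s), normalized by m g."""
    model = model or traj.model
    if model is None:
        raise ValueError("eval_contact_tracking: trajectory carries no model")
    sides = model.foot_sides
    if not sides:
        raise ValueError("eval_contact_tracking: model has no contact feet")
    totals = model.foot_contact_totals(traj.q, traj.u)
    meas = ref.forces_at(traj.time, sides)
    err2 = np.zeros(traj.time.size)
    for j, side in enumerate(sides):
        err2 += ((totals[side] - meas[:, j]) ** 2).sum(axis=1)
    mg = model.total_mass * model.gravity
    return _integrate(err2, traj.time) / mg


def eval_synergy(traj, groups):
    """Within-group excitation synergy cost (s).

    groups: dict gid -> MuscleGroup (or an iterable of groups).  Pairs use one
    squared difference, triples two; singleton groups contribute zero.
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    idx = {nm: j for j, nm in enumerate(traj.muscle_names)}
    per_node = np.zeros(traj.time.size)
    for g in groups:
        members = [m for m in g.members if m in idx]
        if len(members) <= 1:
            logger.debug("synergy: group %s has %d trajectory member(s); contributes 0",
                         g.gid, len(members))
            continue
        e1 = traj.excitation[:, idx[members[0]]]
        per_node += (e1 - traj.excitation[:, idx[members[1]]]) ** 2
        if len(members) == 3:
            per_node += (e1 - traj.excitation[:, idx[members[2]]]) ** 2
    return _integrate(per_node, traj.time)


def eval_effort(traj, weights, com_distance=None, divide_by_distance=False,
                model=None):
    """Control effort over all channels (muscles and actuators).

    With ``divide_by_distance`` the integral is normalized by the CoM travel
    distance d (the predictive form); otherwise the raw integral is returned
    and the composition multiplies by d.
    """
    model = model or traj.model
    if model is not None:
        wm, wa = weights.control_weights(
            model, active_actuators=traj.actuator_names
            if len(traj.actuator_names) != model.n_act else None)
        wm = np.array([wm[model.muscle_index[nm]] if nm in model.muscle_index
                       else weights.muscle_weight for nm in traj.muscle_names])
    else:
        wm = np.full(len(traj.muscle_names), weights.muscle_weight)
        wa = np.full(len(traj.actuator_names),
                     weights.muscle_weight * weights.reserve_penalty)
    per_node = (traj.excitation**2) @ wm
    if traj.actuator.shape[1]:
        per_node = per_node + (traj.actuator**2) @ wa
    J = _integrate(per_node, traj.time)
    if divide_by_distance:
        if com_distance is None or not com_distance > 0:
            raise ValueError(
                "eval_effort: com_distance must be > 0 when divide_by_distance is set"
            )
        J /= com_distance
    return J


_ENERGY_CHANNELS = ("rect_abd", "ext_obl")
_ENERGY_GAIN = 10.0


def eval_energy_penalty(traj):
    """Excess-energy-injection penalty on the abdominal channels (s); zero
    when the model omits them (the planar fixture does)."""
    per_node = np.zeros(traj.time.size)
    for j, nm in enumerate(traj.muscle_names):
        if any(tag in nm.lower() for tag in _ENERGY_CHANNELS):
            per_node += _ENERGY_GAIN * traj.excitation[:, j] ** 2
    return _integrate(per_node, traj.time)


def eval_aux_deriv(traj):
    """Implicit-auxiliary-derivative cost (N^2/s) on tendon-force states;
    zero (logged) in rigid-tendon mode where no such states exist."""
    if traj.tendon_force is None or traj.tendon_force.shape[1] == 0:
        logger.debug("aux-deriv cost: rigid-tendon trajectory, contributes 0")
        return 0.0
    dF = np.gradient(traj.tendon_force, traj.time, axis=0)
    return _integrate((dF**2).sum(axis=1), traj.time)


# ------------------------------------------------------------- composition ---
TRACKING_SUBTERMS = ("J_mt", "J_ct", "J_s", "J_e", "J_p", "J_ad")
PREDICTIVE_SUBTERMS = ("J_s", "J_e", "J_p", "J_ad")


def compose_cost(subterms, weights, mode, d=None):
    """Weighted total cost.

    tracking:   w_mt J_mt + w_ct J_ct + w_s J_s + d w_e J_e + w_p J_p + w_ad J_ad
    predictive: w_s J_s + w_e J_e + w_p J_p + w_ad J_ad
    (in predictive mode J_e is expected to carry its own 1/d factor).
    """
    if mode == "tracking":
        missing = [k for k in ("J_mt", "J_ct") if k not in subterms]
        if missing:
            raise ValueError(
                f"tracking composition requires reference-data subterms {missing}"
            )
        if d is None or not d > 0:
            raise ValueError("tracking composition requires CoM distance d > 0")
        return (
            weights.w_mt * subterms["J_mt"]
            + weights.w_ct * subterms["J_ct"]
            + weights.w_s * subterms.get("J_s", 0.0)
            + d * weights.w_e * subterms.get("J_e", 0.0)
            + weights.w_p * subterms.get("J_p", 0.0)
            + weights.w_ad * subterms.get("J_ad", 0.0)
        )
    if mode == "predictive":
        return (
            weights.w_s * subterms.get("J_s", 0.0)
            + weights.w_e * subterms.get("J_e", 0.0)
            + weights.w_p * subterms.get("J_p", 0.0)
            + weights.w_ad * subterms.get("J_ad", 0.0)
        )
    raise ValueError(f"unknown cost mode {mode!r}")


def cost_report(subterms, weights, mode, d=None, total=None):
    """JSON-ready cost report: per-subterm values, weights, total."""
    if total is None:
        total = compose_cost(subterms, weights, mode, d=d)
    return {
        "mode": mode,
        "subterms": {k: float(v) for k, v in subterms.items()},
        "weights": {k: float(getattr(weights, k)) for k in
                    ("w_mt", "w_ct", "w_s", "w_e", "w_p", "w_ad",
                     "muscle_weight", "reserve_penalty")},
        "com_distance": None if d is None else float(d),
        "total": float(total),
    }
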