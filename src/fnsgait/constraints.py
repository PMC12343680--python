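"""Constraint families for the optimal-control problems.

Eight constraint kinds are supported: half- and full-stride symmetry
endpoints, per-node joint-speed bounds (a percentage of the reference range),
average center-of-mass speed, final-time bounds, leg-intersection clearance,
straight knees at double-stance onset, and an initial-rest condition.  Each is
implemented as a residual/bound generator that a transcription attaches to the
nonlinear program; the functions here also evaluate the residuals on finished
trajectories for reporting.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConstraintSpec",
    "symmetry_residual",
    "speed_bounds",
    "avg_speed_residual",
    "leg_clearance_residual",
    "knee_extension_event",
    "initial_rest_residual",
    "DEFAULT_KNEE_TOLERANCE",
    "DEFAULT_MIN_GAP",
    "DOUBLE_STANCE_BW_FRACTION",
]

CONSTRAINT_KINDS = (
    "sym_half", "sym_full", "speed_bound", "avg_speed", "tf_bound",
    "intersect", "knees", "rest",
)

DEFAULT_KNEE_TOLERANCE = np.deg2rad(1.0)  # rad
DEFAULT_MIN_GAP = 0.05  # m
DOUBLE_STANCE_BW_FRACTION = 0.05  # footstrike threshold as fraction of body weight


@dataclass
class ConstraintSpec:
    """Declarative constraint: kind plus parameters.

    parameters by kind:
      speed_bound: {"percent": fraction}
      avg_speed:   {"target": m/s}
      tf_bound:    {"bounds": (lo, hi) s}
      intersect:   {"min_gap": m}
      knees:       {"tolerance": rad, "both_knees": bool}
      sym_half:    {"exemptions": [channel globs]}  (only kind allowing them)
      sym_full:    {"exemptions": [...]} limited to the travel coordinate
    """

    kind: str
    parameters: dict = field(default_factory=dict)
    exemptions: tuple = ()

    def __post_init__(self):
        if self.kind not in CONSTRAINT_KINDS:
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        for key in ("percent", "target", "min_gap", "tolerance"):
            if key in self.parameters and key != "target" and not self.parameters[key] > 0:
                raise ValueError(f"constraint {self.kind}: parameter {key} must be > 0")
        if self.exemptions and self.kind not in ("sym_half", "sym_full"):
            raise ValueError(f"constraint {self.kind}: exemptions only apply to symmetry")


# ----------------------------------------------------------------- symmetry --
def _channel_labels(traj):
    labels = []
    labels += [f"q/{n}" for n in traj.coord_names]
    labels += [f"u/{n}" for n in traj.coord_names]
    labels += [f"a/{n}" for n in traj.muscle_names]
    labels += [f"e/{n}" for n in traj.muscle_names]
    labels += [f"r/{n}" for n in traj.actuator_names]
    return labels


def default_half_exemptions(model):
    """Travel coordinate position, reserve/volitional actuator channels
    (user-controlled walker interaction and trunk effort), and any sided
    muscle without a contralateral twin (asymmetric muscle sets are solved
    with full-stride symmetry instead)."""
    ex = [f"r/{a.name}" for a in model.actuators]
    for c in model.coords:
        if c.kind == "tx":
            ex.append(f"q/{c.name}")
    for i, nm in enumerate(model.muscle_names):
        if model.muscle_mirror[i] == i and nm[-2:] in ("_l", "_r"):
            ex += [f"a/{nm}", f"e/{nm}"]
    return tuple(ex)


def default_full_exemptions(model):
    return tuple(f"q/{c.name}" for c in model.coords if c.kind == "tx")


def _is_exempt(label, exemptions):
    return any(fnmatch.fnmatch(label, pat) for pat in exemptions)


def symmetry_residual(traj, mode, exemptions=None, model=None):
    """Endpoint symmetry residual.

    half: final state/controls must equal the left/right-mirrored initial
    values; full: final must equal initial (periodicity).  Returns
    (residual vector, channel labels).  Channels matching an exemption glob
    are skipped.  In half mode, any non-exempt sided channel without a
    contralateral twin raises a named error.
    """
    model = model or traj.model
    if model is None:
        raise ValueError("symmetry_residual: trajectory carries no model")
    if mode not in ("half", "full"):
        raise ValueError(f"symmetry_residual: unknown mode {mode!r}")
    if exemptions is None:
        exemptions = (default_half_exemptions(model) if mode == "half"
                      else default_full_exemptions(model))

    start = np.concatenate([traj.q[0], traj.u[0], traj.a[0],
                            traj.excitation[0], traj.actuator[0]])
    end = np.concatenate([traj.q[-1], traj.u[-1], traj.a[-1],
                          traj.excitation[-1], traj.actuator[-1]])
    labels = _channel_labels(traj)

    if mode == "full":
        keep = [i for i, lb in enumerate(labels) if not _is_exempt(lb, exemptions)]
        return end[keep] - start[keep], [labels[i] for i in keep]

    # half: build the mirrored start vector channel by channel.
    def mirrored_names(names, kind):
        perm = []
        for nm in names:
            if nm.endswith("_l"):
                twin = nm[:-2] + "_r"
            elif nm.endswith("_r"):
                twin = nm[:-2] + "_l"
            elif "_l_" in nm:
                twin = nm.replace("_l_", "_r_")
            elif "_r_" in nm:
                twin = nm.replace("_r_", "_l_")
            else:
                twin = nm
            if twin not in names:
                if _is_exempt(f"{kind}/{nm}", exemptions):
                    perm.append(nm)  # exempted anyway
                    continue
                raise ValueError(
                    f"half-stride symmetry: channel {kind}/{nm} has no "
                    f"contralateral twin {twin!r} and is not exempted"
                )
            perm.append(twin)
        return perm

    cm = mirrored_names(traj.coord_names, "q")
    mm = mirrored_names(traj.muscle_names, "e")
    am = mirrored_names(traj.actuator_names, "r")
    ci = {n: i for i, n in enumerate(traj.coord_names)}
    mi = {n: i for i, n in enumerate(traj.muscle_names)}
    ai = {n: i for i, n in enumerate(traj.actuator_names)}
    perm = ([ci[n] for n in cm] + [len(ci) + ci[n] for n in cm]
            + [2 * len(ci) + mi[n] for n in mm]
            + [2 * len(ci) + len(mi) + mi[n] for n in mm]
            + [2 * len(ci) + 2 * len(mi) + ai[n] for n in am])
    mirrored_start = start[np.array(perm, dtype=int)]
    keep = [i for i, lb in enumerate(labels) if not _is_exempt(lb, exemptions)]
    return end[keep] - mirrored_start[keep], [labels[i] for i in keep]


# -------------------------------------------------------------- speed bound --
def speed_bounds(nt_speed_ranges, percent):
    """Per-coordinate speed bounds: percent of the reference (NT inverse
    kinematics) speed range, applied at every mesh node.

    nt_speed_ranges: dict coord -> (lo, hi).  The bounds are symmetric:
    +- percent times the range magnitude max(|lo|, |hi|), so rest (zero
    speed) always lies inside them.  A zero-magnitude range is flagged in
    the log and left degenerate (the transcription falls back to the
    coordinate's physical speed range).
    """
    if not percent > 0:
        raise ValueError("speed_bounds: percent must be > 0")
    out = {}
    for coord, (lo, hi) in nt_speed_ranges.items():
        mag = max(abs(lo), abs(hi))
        if np.isclose(mag, 0.0):
            logger.warning("speed_bounds: degenerate reference speed range for %s", coord)
        out[coord] = (-percent * mag, percent * mag)
    return out


# ---------------------------------------------------------------- avg speed --
def avg_speed_residual(traj, target, model=None):
    """(CoM_x(t_f) - CoM_x(t_i)) / (t_f - t_i) - target (m/s)."""
    model = model or traj.model
    if model is None:
        raise ValueError("avg_speed_residual: trajectory carries no model")
    if traj.t_f <= traj.t_i:
        raise ValueError("avg_speed_residual: t_f must exceed t_i")
    com = model.com_position(np.vstack([traj.q[0], traj.q[-1]]))
    return float((com[1, 0] - com[0, 0]) / traj.duration - target)


# ---------------------------------------------------------------- clearance --
def leg_clearance_residual(traj, min_gap=DEFAULT_MIN_GAP, model=None):
    """Per-node gap between the designated left/right leg landmark points
    minus min_gap (>= 0 required).  The gap is the planar distance in the
    (anterior-posterior, lateral) plane and is symmetric under left/right
    exchange."""
    model = model or traj.model
    if model is None:
        raise ValueError("leg_clearance_residual: trajectory carries no model")
    pl, pr, lat_l, lat_r = model.leg_landmark_points(traj.q)
    gap = np.sqrt((pl[:, 0] - pr[:, 0]) ** 2 + (lat_l - lat_r) ** 2)
    return gap - min_gap


# -------------------------------------------------------------------- knees --
def knee_extension_event(traj, tolerance=DEFAULT_KNEE_TOLERANCE, model=None,
                         bw_fraction=DOUBLE_STANCE_BW_FRACTION, both_knees=True):
    """Residuals |knee angle| - tolerance at double-stance onsets.

    Onsets are the nodes where a foot's total normal contact force first
    exceeds ``bw_fraction`` of body weight while the contralateral foot is
    already loaded.  Returns (residuals, labels); residuals <= 0 are
    satisfied.  Raises a named error when no double stance is found.
    """
    model = model or traj.model
    if model is None:
        raise ValueError("knee_extension_event: trajectory carries no model")
    totals = model.foot_contact_totals(traj.q, traj.u)
    thr = bw_fraction * model.total_mass * model.gravity
    loaded = {s: totals[s][:, 1] > thr for s in model.foot_sides}
    onsets = []
    for s in model.foot_sides:
        other = [o for o in model.foot_sides if o != s]
        ld = loaded[s]
        strikes = np.where(~ld[:-1] & ld[1:])[0] + 1
        for k in strikes:
            if all(loaded[o][k] for o in other):
                onsets.append((k, s))
    if not onsets:
        raise ValueError("knee_extension_event: no double-stance onset found in trajectory")
    knee_cols = {s: traj.coord_names.index(f"knee_{s[0]}") for s in model.foot_sides}
    residuals, labels = [], []
    for k, striking in onsets:
        sides = model.foot_sides if both_knees else [striking]
        for s in sides:
            ang = traj.q[k, knee_cols[s]]
            residuals.append(abs(ang) - tolerance)
            labels.append(f"node{k}/knee_{s[0]}")
    return np.array(residuals), labels


# --------------------------------------------------------------------- rest --
def initial_rest_residual(traj):
    """Full speed vector at t_i (zero when the model starts at rest)."""
    return traj.u[0].copy()
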