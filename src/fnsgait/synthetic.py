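"""Synthetic inputs with known ground truth.

Three generators cover every external input the pipeline needs:

* :func:`generate_nt_reference` — neurotypical-style reference data for the
  tracking stage: smooth periodic joint-angle templates (truncated Fourier
  series) pushed through the model's forward kinematics to give marker
  trajectories advancing at the stated speed, plus double-bump vertical
  ground-reaction forces alternating at the stated cadence whose vertical
  impulse per stride equals body weight times stride time.
* :func:`generate_trial` — a recorded stepping trial (markers, walker handle
  forces, step events) realized to match the requested per-side step time,
  step length and swing/stance ratio exactly before noise; the matching
  ground-truth step records are returned alongside.
* :func:`generate_excitations` — muscle-group excitation traces (transient
  bursts) within the [0.01, 1] normalization.

All randomness flows from one explicit seed per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .costs import ReferenceData
from .gait import AP, ML, VERT, GaitTrial, StepRecord

__all__ = [
    "NTReferenceSpec",
    "TrialSpec",
    "generate_nt_reference",
    "generate_trial",
    "generate_excitations",
]


@dataclass
class NTReferenceSpec:
    """Neurotypical reference conditions: a slow self-selected overground
    pace.  speed = stride_length / stride_time is enforced."""

    gait_speed: float = 0.4  # m/s
    cadence: float = 120.0  # steps/min
    stride_length: float | None = None  # m; derived from speed and cadence
    grf_peak_bw: float = 1.1  # informational; impulse normalization dominates
    marker_rate: float = 100.0  # Hz
    force_rate: float = 1000.0  # Hz
    n_strides: float = 1.2
    body_mass: float = 76.2  # kg
    stance_fraction: float = 0.6
    hip_amplitude: float = 0.25  # rad
    knee_amplitude: float = 0.7  # rad
    ankle_amplitude: float = 0.15  # rad
    # Stand-in for inverse-kinematics speed ranges: raw differentiated IK
    # carries high-frequency content roughly an order of magnitude above the
    # smooth underlying motion, so the reported range is the template-speed
    # extreme times this factor (a stated percentage of the range then
    # admits the reference motion itself).
    ik_speed_range_factor: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.marker_rate <= 0 or self.force_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        st = self.stride_time
        derived = self.gait_speed * st
        if self.stride_length is None:
            self.stride_length = derived
        elif not np.isclose(self.stride_length, derived, rtol=1e-6, atol=1e-9):
            raise ValueError(
                f"inconsistent spec: stride_length {self.stride_length} != "
                f"speed x stride_time = {derived}"
            )

    @property
    def stride_time(self):
        return 2.0 * 60.0 / self.cadence  # two steps per stride


def _joint_templates(spec, phase):
    """Smooth periodic joint-angle templates (rad) per coordinate, given the
    left-stride phase array in [0, inf)."""
    two_pi = 2.0 * np.pi
    phl = phase
    phr = phase + 0.5

    def knee(ph):
        x = two_pi * (ph - 0.75)
        return spec.knee_amplitude * (0.375 - 0.5 * np.cos(x) + 0.125 * np.cos(2 * x))

    return {
        "hip_l": 0.05 + spec.hip_amplitude * np.cos(two_pi * phl),
        "hip_r": 0.05 + spec.hip_amplitude * np.cos(two_pi * phr),
        "knee_l": knee(phl),
        "knee_r": knee(phr),
        "ankle_l": spec.ankle_amplitude * np.sin(two_pi * phl),
        "ankle_r": spec.ankle_amplitude * np.sin(two_pi * phr),
        "pelvis_rot": 0.05 + 0.02 * np.sin(two_pi * phl),
        "trunk_pitch": 0.03 * np.sin(two_pi * phl + 1.0),
        "pelvis_ty": 0.93 + 0.01 * np.cos(2 * two_pi * phl),
    }


def generate_nt_reference(spec: NTReferenceSpec, model=None) -> ReferenceData:
    """Synthesize tracking reference data (markers + per-foot GRF).

    With a model, marker trajectories are its forward kinematics evaluated on
    the joint templates, so the reference is kinematically consistent with
    the model geometry; without one, generic markers follow truncated Fourier
    series directly.
    """
    T = spec.stride_time
    duration = spec.n_strides * T
    tm = np.arange(0.0, duration + 0.5 / spec.marker_rate, 1.0 / spec.marker_rate)
    tf_ = np.arange(0.0, duration + 0.5 / spec.force_rate, 1.0 / spec.force_rate)
    phase_m = tm / T
    rng = np.random.default_rng(spec.seed)

    if model is not None:
        templ = _joint_templates(spec, phase_m)
        Q = np.zeros((tm.size, model.n_q))
        for name, vals in templ.items():
            if name in model.coord_index:
                Q[:, model.coord_index[name]] = vals
        itx = model.coord_index.get("pelvis_tx")
        if itx is not None:
            Q[:, itx] = spec.gait_speed * tm + 0.01 * np.sin(2 * np.pi * phase_m)
        marker_xy = model.marker_positions(Q)
        marker_names = [mk.name for mk in model.markers]
        # Reference joint-speed ranges (the synthetic stand-in for ranges
        # computed from inverse kinematics of the reference motion).
        U = np.gradient(Q, tm, axis=0)
        f = spec.ik_speed_range_factor
        nt_ranges = {model.coord_names[j]: (f * float(U[:, j].min()),
                                            f * float(U[:, j].max()))
                     for j in range(model.n_q)}
    else:
        marker_names = ["M1", "M2", "M3", "M4"]
        base = rng.uniform(-0.3, 0.3, (len(marker_names), 2)) + np.array([0.0, 1.0])
        amp = rng.uniform(0.02, 0.06, (len(marker_names), 2, 2))
        phases = rng.uniform(0, 2 * np.pi, (len(marker_names), 2, 2))
        marker_xy = np.zeros((tm.size, len(marker_names), 2))
        for k in range(len(marker_names)):
            for d in range(2):
                marker_xy[:, k, d] = base[k, d]
                for h in range(2):
                    marker_xy[:, k, d] += amp[k, d, h] * np.cos(
                        2 * np.pi * (h + 1) * phase_m + phases[k, d, h]
                    )
            marker_xy[:, k, 0] += spec.gait_speed * tm
        nt_ranges = {}

    # Per-foot vertical GRF: double-bump during stance, alternating sides;
    # anterior-posterior braking/propulsion wave.  The summed vertical
    # impulse per stride is normalized to body weight x stride time.
    bw = spec.body_mass * 9.81
    phase_f = tf_ / T

    def grf(ph_side):
        s = np.mod(ph_side, 1.0) / spec.stance_fraction
        in_stance = s < 1.0
        s = np.clip(s, 0.0, 1.0)
        fz = np.where(in_stance, np.sin(np.pi * s) + 0.25 * np.sin(3 * np.pi * s), 0.0)
        fx = np.where(in_stance, -np.sin(2 * np.pi * s) * np.sin(np.pi * s), 0.0)
        return fx, fz

    fxl, fzl = grf(phase_f)
    fxr, fzr = grf(phase_f + 0.5)
    total = fzl + fzr
    dt = 1.0 / spec.force_rate
    # Normalize on one full stride.
    n_stride = int(round(T * spec.force_rate))
    impulse = np.sum(total[:n_stride]) * dt
    scale = bw * T / impulse
    force_xy = np.zeros((tf_.size, 2, 2))
    force_xy[:, 0, 0] = 0.15 * bw * fxl
    force_xy[:, 0, 1] = scale * fzl
    force_xy[:, 1, 0] = 0.15 * bw * fxr
    force_xy[:, 1, 1] = scale * fzr

    return ReferenceData(
        marker_time=tm, marker_names=marker_names, marker_xy=marker_xy,
        force_time=tf_, force_sides=["left", "right"], force_xy=force_xy,
        marker_rate=spec.marker_rate, force_rate=spec.force_rate,
        nt_speed_ranges=nt_ranges,
        meta={"stride_time": T, "gait_speed": spec.gait_speed,
              "cadence": spec.cadence, "body_mass": spec.body_mass},
    )


# ------------------------------------------------------------------ trials ---
@dataclass
class TrialSpec:
    """Synthetic stepping-trial conditions.  Defaults mirror the magnitudes
    of slow FNS-assisted stepping with long double-stance pauses."""

    step_time: dict = field(default_factory=lambda: {"left": 16.85, "right": 16.80})  # s
    step_length: dict = field(default_factory=lambda: {"left": 0.539, "right": 0.538})  # m
    swing_stance_ratio: dict = field(default_factory=lambda: {"left": 0.13, "right": 0.15})
    uee_baseline: float = 150.0  # N
    uee_swing_peak: dict = field(default_factory=lambda: {"left": 300.0, "right": 360.0})  # N
    n_steps: int = 6  # per side
    marker_rate: float = 100.0
    force_rate: float = 1000.0
    noise_marker_sd: float = 0.0  # m (typical motion capture: 0.002)
    noise_force_sd: float = 0.0  # N (typical load cell: 2.0)
    walker_ml_velocity: float = 0.05  # m/s nominal per-step feature
    outliers: list = field(default_factory=list)  # {"side","step","feature","value"}
    pattern: str = "optimized"
    trial_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        for d in (self.step_time, self.step_length, self.swing_stance_ratio,
                  self.uee_swing_peak):
            for v in d.values():
                if not v > 0:
                    raise ValueError("trial spec values must be positive")


def _smoothstep(s):
    return s * s * (3.0 - 2.0 * s)


def generate_trial(spec: TrialSpec):
    """Build a GaitTrial plus its ground-truth StepRecord list.

    Heel markers dwell at each footfall through stance and advance by one
    stride during swing (smoothstep, zero end slope), so step lengths and
    event-derived times are recovered exactly by the analyzer on noiseless
    data.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    dt_m = 1.0 / spec.marker_rate
    t0 = 0.5
    TL, TR = spec.step_time["left"], spec.step_time["right"]
    LL, LR = spec.step_length["left"], spec.step_length["right"]
    stride_adv = LL + LR

    # Event times; snap footstrikes to the marker sampling grid so marker
    # interpolation at footstrike hits the dwell positions exactly.
    def snap(t):
        return np.round(t / dt_m) * dt_m

    n = spec.n_steps
    fs = {"left": snap(t0 + TL * np.arange(n + 1)),
          "right": snap(t0 + 0.5 * min(TL, TR) + TR * np.arange(n + 1))}
    events = {}
    for side, T in (("left", TL), ("right", TR)):
        ratio = spec.swing_stance_ratio[side]
        stance = T / (1.0 + ratio)
        events[side] = {
            "footstrike": fs[side].tolist(),
            "toeoff": (fs[side][:-1] + stance).tolist(),
        }

    # Footfall positions: x_R,k - x_L,k = LR ; x_L,k+1 - x_R,k = LL.
    place = {"left": stride_adv * np.arange(n + 2),
             "right": stride_adv * np.arange(n + 2) + LR}

    t_end = max(fs["left"][-1], fs["right"][-1]) + 2.0
    tm = np.arange(0.0, t_end, dt_m)
    tf_ = np.arange(0.0, t_end, 1.0 / spec.force_rate)

    marker_names = ["HEEL_L", "TOE_L", "HEEL_R", "TOE_R"]
    xyz = np.zeros((tm.size, 4, 3))

    toe_offset = 0.22
    outlier_toe = {(o["side"], o["step"]): o["value"] for o in spec.outliers
                   if o["feature"] == "toe_travel_ap"}

    for side, heel_col, toe_col, lat in (("left", 0, 1, 0.12), ("right", 2, 3, -0.12)):
        heel_ap = np.empty(tm.size)
        heel_v = np.full(tm.size, 0.03)
        toe_ap = np.empty(tm.size)
        toe_v = np.full(tm.size, 0.02)
        fss = fs[side]
        tos = np.asarray(events[side]["toeoff"])
        heel_ap[tm < fss[0]] = place[side][0]
        toe_ap[tm < fss[0]] = place[side][0] + toe_offset
        for k in range(len(fss)):
            # stance dwell
            t_a = fss[k]
            t_b = tos[k] if k < len(tos) else t_end
            m = (tm >= t_a) & (tm < t_b)
            heel_ap[m] = place[side][k]
            toe_ap[m] = place[side][k] + toe_offset
            if k < len(tos):
                # swing advance
                t_c = fss[k + 1]
                m = (tm >= t_b) & (tm < t_c)
                s = (tm[m] - t_b) / (t_c - t_b)
                heel_ap[m] = place[side][k] + stride_adv * _smoothstep(s)
                toe_adv = outlier_toe.get((side, k), stride_adv)
                toe_ap[m] = place[side][k] + toe_offset + toe_adv * _smoothstep(s)
                heel_v[m] += 0.05 * np.sin(np.pi * s) ** 2
                toe_v[m] += 0.06 * np.sin(np.pi * np.clip(s * 1.1, 0, 1)) ** 2
        tail = tm >= fss[-1]
        heel_ap[tail] = place[side][len(fss) - 1]
        toe_ap[tail] = place[side][len(fss) - 1] + toe_offset
        xyz[:, heel_col, AP] = heel_ap
        xyz[:, heel_col, VERT] = heel_v
        xyz[:, heel_col, ML] = lat
        xyz[:, toe_col, AP] = toe_ap
        xyz[:, toe_col, VERT] = toe_v
        xyz[:, toe_col, ML] = lat

    # Handle forces: vertical baseline plus a sin^2 bump peaking mid-swing.
    fy = np.full(tf_.size, spec.uee_baseline)
    for side in ("left", "right"):
        peak = spec.uee_swing_peak[side]
        tos = np.asarray(events[side]["toeoff"])
        fss = fs[side]
        for k in range(len(tos)):
            t_b, t_c = tos[k], fss[k + 1]
            m = (tf_ >= t_b) & (tf_ <= t_c)
            s = (tf_[m] - t_b) / (t_c - t_b)
            fy[m] = spec.uee_baseline + (peak - spec.uee_baseline) * np.sin(np.pi * s) ** 2
    handle = np.zeros((tf_.size, 3))
    handle[:, 1] = 0.5 * fy
    forces = {"left": handle.copy(), "right": handle.copy()}

    # Per-step walker medial-lateral velocity feature.
    wml = {}
    for side in ("left", "right"):
        vals = np.full(spec.n_steps, spec.walker_ml_velocity)
        for o in spec.outliers:
            if o["feature"] == "ml_walker_velocity" and o["side"] == side:
                vals[o["step"]] = o["value"]
        wml[side] = vals.tolist()

    if spec.noise_marker_sd > 0:
        xyz = xyz + rng.normal(0.0, spec.noise_marker_sd, xyz.shape)
    if spec.noise_force_sd > 0:
        for side in forces:
            forces[side] = forces[side] + rng.normal(0.0, spec.noise_force_sd,
                                                     forces[side].shape)

    trial = GaitTrial(
        marker_time=tm, marker_names=marker_names, marker_xyz=xyz,
        force_time=tf_, handle_forces=forces, events=events,
        pattern=spec.pattern, trial_id=spec.trial_id, walker_ml_velocity=wml,
        meta={"spec": spec},
    )

    truth = []
    for side in ("left", "right"):
        T = spec.step_time[side]
        ratio = spec.swing_stance_ratio[side]
        stance = T / (1.0 + ratio)
        for k in range(spec.n_steps):
            fs_k, fs_k1 = fs[side][k], fs[side][k + 1]
            step_time = fs_k1 - fs_k
            truth.append(StepRecord(
                side=side, step_time=float(step_time),
                step_length=spec.step_length[side],
                swing_time=float(fs_k1 - (fs_k + stance)), stance_time=float(stance),
                swing_stance_ratio=float((fs_k1 - (fs_k + stance)) / stance),
                peak_uee=spec.uee_baseline + 0.0 + max(
                    spec.uee_swing_peak[side] - spec.uee_baseline, 0.0),
                peak_uee_swing=spec.uee_swing_peak[side],
                mean_uee_swing=spec.uee_baseline
                + 0.5 * (spec.uee_swing_peak[side] - spec.uee_baseline),
                ml_walker_velocity=wml[side][k],
                toe_travel_ap=outlier_toe.get((side, k), stride_adv),
                t_start=float(fs_k), t_end=float(fs_k1),
                t_toeoff=float(fs_k + stance), trial_id=spec.trial_id,
            ))
    return trial, truth


# ------------------------------------------------------------- excitations ---
def generate_excitations(groups, duration, shape="pulse", seed=0, synergy=True,
                         n_samples=101, amplitude=1.0, lo=0.01):
    """Excitation traces per muscle group, within [0.01, 1].

    groups: dict gid -> MuscleGroup (or iterable).  With synergy=True all
    members of a group share one trace (the group synergy cost is zero);
    otherwise members get independent burst timings.  Returns (time,
    {muscle_name: trace}).
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if isinstance(groups, dict):
        groups = list(groups.values())
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_samples)

    def burst(center, width):
        s = np.clip((t - (center - width / 2)) / width, 0.0, 1.0)
        return np.sin(np.pi * s) ** 2

    traces = {}
    for g in groups:
        if shape == "pulse":
            base = burst(rng.uniform(0.25, 0.75) * duration, 0.4 * duration)
        elif shape == "ramp":
            base = t / duration
        elif callable(shape):
            base = np.clip(np.asarray(shape(t), dtype=float), 0.0, 1.0)
        else:
            raise ValueError(f"unknown excitation shape {shape!r}")
        for m in g.members:
            if synergy:
                e = base
            else:
                jitter = rng.uniform(-0.1, 0.1) * duration
                e = np.interp(t - jitter, t, base)
            traces[m] = np.clip(lo + (amplitude - lo) * e, lo, 1.0)
    return t, traces
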