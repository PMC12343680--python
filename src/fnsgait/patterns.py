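"""Stimulation-pattern compilation and charge accounting.

Optimized muscle excitations become device-ready pulse-width (PW) schedules:
each side's group excitations are extracted from its half of the two-step
cycle (stance portions discarded), averaged across group elements, resampled
to 22 points by linear interpolation, and mapped to PW through the channel
calibration

    PW = excitation * Sat + Thresh   (µs, clamped to the 0-255 device range).

Strength-matching scalings follow: left-side PWs x 1.2 (re-clamped), right
side time base x 1.5.  The pulse frequency starts at 16 Hz and doubles after
0.15 s for every muscle except the vasti; on the right side it returns to
16 Hz for the final 30% of the pattern.  Charge per swing is pulse amplitude
times PW summed over the delivered pulses (cathodic phase), in µC.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelCalibration",
    "StimulationPattern",
    "ChargeReport",
    "extract_swing_excitations",
    "compile_pattern",
    "build_frequency_schedule",
    "charge_per_swing",
    "compare_patterns",
    "export_patterns",
    "import_patterns",
    "PW_LIMIT_US",
    "N_PATTERN_SAMPLES",
]

PW_LIMIT_US = 255.0
N_PATTERN_SAMPLES = 22
AMPLITUDE_LIMITS_MA = {"implanted": (0.0, 20.0), "surface": (0.0, 100.0)}
BASE_FREQUENCY_HZ = 16.0
HIGH_FREQUENCY_HZ = 32.0
FREQUENCY_SWITCH_S = 0.15
RIGHT_TAIL_FRACTION = 0.30  # "approximately 30%" implemented as exactly 30%
LEFT_PW_GAIN = 1.2
RIGHT_TIME_GAIN = 1.5


@dataclass
class ChannelCalibration:
    """Per-channel stimulation calibration (therapist-identified)."""

    channel: str  # channel id, conventionally the muscle-group id
    muscle_group: str
    side: str  # "left" | "right"
    method: str  # "implanted" | "surface"
    sat: float  # µs, excitation-to-PW slope
    thresh: float  # µs, PW offset
    amplitude: float  # mA, constant per channel
    clamp: bool = True  # allow thresh + sat beyond 255 only when clamping

    def __post_init__(self):
        if self.method not in AMPLITUDE_LIMITS_MA:
            raise ValueError(f"channel {self.channel}: unknown method {self.method!r}")
        if self.thresh < 0:
            raise ValueError(f"channel {self.channel}: Thresh must be >= 0")
        if not self.sat > 0:
            raise ValueError(f"channel {self.channel}: Sat must be > 0")
        lo, hi = AMPLITUDE_LIMITS_MA[self.method]
        if not lo <= self.amplitude <= hi:
            raise ValueError(
                f"channel {self.channel}: amplitude {self.amplitude} mA outside "
                f"{self.method} limits {AMPLITUDE_LIMITS_MA[self.method]}"
            )
        if self.thresh + self.sat > PW_LIMIT_US and not self.clamp:
            raise ValueError(
                f"channel {self.channel}: Thresh + Sat exceeds {PW_LIMIT_US} µs "
                "and clamping is disabled"
            )


@dataclass
class StimulationPattern:
    """One channel's compiled pattern: 22 PW samples on its time base, a
    piecewise-constant frequency schedule, and the channel amplitude."""

    channel: str
    side: str
    muscle_group: str
    sample_times: np.ndarray  # (22,) s
    pw_us: np.ndarray  # (22,) µs in [0, 255]
    amplitude_ma: float
    frequency_schedule: list  # [(t0, t1, hz)]
    swing_duration: float  # s
    provenance: dict = field(default_factory=dict)  # calibration used, gains

    def __post_init__(self):
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.pw_us = np.asarray(self.pw_us, dtype=float)
        if self.pw_us.shape != (N_PATTERN_SAMPLES,) or \
                self.sample_times.shape != (N_PATTERN_SAMPLES,):
            raise ValueError(
                f"pattern {self.channel}: exactly {N_PATTERN_SAMPLES} samples required"
            )
        if np.any(self.pw_us < -1e-9) or np.any(self.pw_us > PW_LIMIT_US + 1e-9):
            raise ValueError(f"pattern {self.channel}: PW outside [0, {PW_LIMIT_US}] µs")
        for _, _, hz in self.frequency_schedule:
            if hz not in (BASE_FREQUENCY_HZ, HIGH_FREQUENCY_HZ):
                raise ValueError(f"pattern {self.channel}: frequency {hz} Hz not in "
                                 f"{{{BASE_FREQUENCY_HZ}, {HIGH_FREQUENCY_HZ}}}")

    def pw_at(self, t):
        return np.interp(t, self.sample_times, self.pw_us)

    def frequency_at(self, t):
        for t0, t1, hz in self.frequency_schedule:
            if t0 - 1e-12 <= t < t1 - 1e-12:
                return hz
        return self.frequency_schedule[-1][2]


@dataclass
class ChargeReport:
    per_muscle: dict  # key -> {"optimized": µC, "manual": µC, "reduction_pct": %}
    mean_reduction_pct: float  # mean over muscles showing a reduction
    min_reduction_pct: float
    max_reduction_pct: float
    increases: dict = field(default_factory=dict)  # key -> % increase
    flagged: list = field(default_factory=list)  # keys with undefined percent


# ------------------------------------------------------------- extraction ---
def extract_swing_excitations(solution, model=None, trim_stance=True,
                              bw_fraction=0.05):
    """Per-side muscle-group excitation traces from a two-step solution.

    Left-side excitations come from the first half of the cycle, right-side
    from the second half; within each half the stance portion (foot loaded
    above ``bw_fraction`` of body weight) is discarded when contact
    information is available.  Group members are averaged into one trace.
    Returns {"left": {gid: (t, e)}, "right": {gid: (t, e)}} with each time
    base starting at zero.
    """
    traj = getattr(solution, "trajectory", solution)
    model = model or traj.model
    if model is None:
        raise ValueError("extract_swing_excitations: trajectory carries no model")
    t_mid = traj.t_i + 0.5 * traj.duration
    windows = {"left": (traj.t_i, t_mid), "right": (t_mid, traj.t_f)}

    loaded = None
    if trim_stance and model.contact_spheres:
        totals = model.foot_contact_totals(traj.q, traj.u)
        thr = bw_fraction * model.total_mass * model.gravity
        loaded = {s: totals[s][:, 1] > thr for s in model.foot_sides}

    idx = {n: j for j, n in enumerate(traj.muscle_names)}
    out = {}
    for side, (t0, t1) in windows.items():
        groups = {g.gid: g for g in model.muscle_groups.values() if g.side == side}
        if not groups:
            raise ValueError(f"extract_swing_excitations: no {side}-side muscle groups")
        mask = (traj.time >= t0 - 1e-12) & (traj.time <= t1 + 1e-12)
        if loaded is not None and side in loaded:
            unl = ~loaded[side] & mask
            if unl.any():
                lo, hi = np.where(unl)[0][[0, -1]]
                mask = np.zeros_like(mask)
                mask[lo:hi + 1] = True
        tw = traj.time[mask]
        side_traces = {}
        for gid, g in groups.items():
            members = [m for m in g.members if m in idx]
            if not members:
                continue
            e = traj.excitation[np.ix_(mask, [idx[m] for m in members])].mean(axis=1)
            side_traces[gid] = (tw - tw[0], e)
        out[side] = side_traces
    return out


# ------------------------------------------------------------ compilation ---
def compile_pattern(excitations, calibrations, left_pw_gain=LEFT_PW_GAIN,
                    right_time_gain=RIGHT_TIME_GAIN):
    """Compile per-side group excitation traces into stimulation patterns.

    excitations: {"left": {gid: (t, e)}, "right": ...} with e in [0, 1].
    calibrations: iterable of ChannelCalibration keyed by muscle group + side.
    Returns {channel id: StimulationPattern}.
    """
    calib_by_key = {(c.muscle_group, c.side): c for c in calibrations}
    patterns = {}
    for side, traces in excitations.items():
        for gid, (t, e) in traces.items():
            t = np.asarray(t, dtype=float)
            e = np.asarray(e, dtype=float)
            if np.any(e < -1e-9) or np.any(e > 1 + 1e-9):
                raise ValueError(f"excitation for {gid} outside [0, 1]")
            cal = calib_by_key.get((gid, side))
            if cal is None:
                raise KeyError(f"no calibration for muscle group {gid!r} on {side} side")
            duration = float(t[-1] - t[0])
            if side == "right":
                duration *= right_time_gain
            times = np.linspace(0.0, duration, N_PATTERN_SAMPLES)
            # Resample in normalized time, then map through the calibration.
            src = (t - t[0]) / (t[-1] - t[0]) if t[-1] > t[0] else np.linspace(0, 1, t.size)
            e22 = np.interp(np.linspace(0.0, 1.0, N_PATTERN_SAMPLES), src, e)
            pw = np.clip(e22 * cal.sat + cal.thresh, 0.0, PW_LIMIT_US)
            if side == "left":
                pw = np.clip(pw * left_pw_gain, 0.0, PW_LIMIT_US)
            patterns[cal.channel] = StimulationPattern(
                channel=cal.channel, side=side, muscle_group=gid,
                sample_times=times, pw_us=pw, amplitude_ma=cal.amplitude,
                frequency_schedule=build_frequency_schedule(side, gid, duration),
                swing_duration=duration,
                provenance={"sat_us": cal.sat, "thresh_us": cal.thresh,
                            "method": cal.method,
                            "left_pw_gain": left_pw_gain if side == "left" else 1.0,
                            "right_time_gain": right_time_gain
                            if side == "right" else 1.0},
            )
    return patterns


def build_frequency_schedule(side, channel_group, swing_duration,
                             base=BASE_FREQUENCY_HZ, high=HIGH_FREQUENCY_HZ,
                             switch=FREQUENCY_SWITCH_S,
                             right_tail_fraction=RIGHT_TAIL_FRACTION,
                             vasti_tag="vasti"):
    """Piecewise-constant frequency schedule [(t0, t1, hz)].

    Vasti channels stay at the base frequency throughout (sufficient knee
    extension force without fatigue risk); other channels double after
    ``switch`` seconds; right-side channels drop back to base for the final
    ``right_tail_fraction`` of the pattern.
    """
    if not swing_duration > 0:
        raise ValueError("swing_duration must be > 0")
    if vasti_tag in channel_group.lower():
        return [(0.0, swing_duration, base)]
    if swing_duration <= switch:
        logger.warning("frequency schedule: pattern of %.3f s never reaches the "
                       "doubled frequency", swing_duration)
        return [(0.0, swing_duration, base)]
    if side == "left":
        return [(0.0, switch, base), (switch, swing_duration, high)]
    t_tail = swing_duration * (1.0 - right_tail_fraction)
    if t_tail <= switch:
        return [(0.0, switch, base), (switch, swing_duration, base)]
    return [(0.0, switch, base), (switch, t_tail, high),
            (t_tail, swing_duration, base)]


# ------------------------------------------------------------------ charge ---
def charge_per_swing(pattern: StimulationPattern):
    """Charge delivered over the swing pattern, µC.

    Pulses start at t = 0 and advance by the instantaneous inter-pulse
    interval; a partial trailing interval delivers no pulse.  Each pulse
    contributes amplitude (mA) x PW (µs) of cathodic charge.
    """
    T = pattern.swing_duration
    t = 0.0
    charge_nc = 0.0
    while t < T - 1e-9:
        charge_nc += pattern.amplitude_ma * pattern.pw_at(t)
        t += 1.0 / pattern.frequency_at(t)
    return charge_nc * 1e-3  # (mA*µs = nC) -> µC


# ------------------------------------------------------------- comparison ---
def compare_patterns(optimized_charges, manual_charges):
    """ChargeReport comparing per-muscle charge of two patterns (µC).

    Percent reduction is 100 * (1 - optimized/manual); negative reductions
    are reported as increases with sign.  The summary mean/min/max cover the
    muscles showing a reduction.  Muscles with zero manual charge are flagged
    (undefined percent).
    """
    if set(optimized_charges) != set(manual_charges):
        raise ValueError("compare_patterns: muscle keys differ between patterns")
    per, reductions, increases, flagged = {}, {}, {}, []
    for key in optimized_charges:
        opt, man = float(optimized_charges[key]), float(manual_charges[key])
        if opt < 0 or man < 0:
            raise ValueError(f"compare_patterns: negative charge for {key}")
        if man == 0.0:
            flagged.append(key)
            per[key] = {"optimized": opt, "manual": man, "reduction_pct": None}
            continue
        red = 100.0 * (1.0 - opt / man)
        per[key] = {"optimized": opt, "manual": man, "reduction_pct": red}
        if red >= 0:
            reductions[key] = red
        else:
            increases[key] = -red
    vals = np.array(list(reductions.values()))
    return ChargeReport(
        per_muscle=per,
        mean_reduction_pct=float(vals.mean()) if vals.size else np.nan,
        min_reduction_pct=float(vals.min()) if vals.size else np.nan,
        max_reduction_pct=float(vals.max()) if vals.size else np.nan,
        increases=increases, flagged=flagged,
    )


# ---------------------------------------------------------------------- IO ---
def export_patterns(patterns, out_dir):
    """Write patterns as CSV (channel, sample_index, time_s, pw_us) plus a
    JSON sidecar (amplitude, frequency schedule, provenance)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "pattern.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["channel", "sample_index", "time_s", "pw_us"])
        for ch, p in sorted(patterns.items()):
            for i in range(N_PATTERN_SAMPLES):
                wr.writerow([ch, i, f"{p.sample_times[i]:.17g}", f"{p.pw_us[i]:.17g}"])
    side = {
        ch: {
            "side": p.side, "muscle_group": p.muscle_group,
            "amplitude_ma": p.amplitude_ma,
            "frequency_schedule": [[t0, t1, hz] for t0, t1, hz in p.frequency_schedule],
            "swing_duration": p.swing_duration,
            "provenance": p.provenance,
        }
        for ch, p in sorted(patterns.items())
    }
    with open(out / "pattern.json", "w") as fh:
        json.dump(side, fh, indent=2)
    return out / "pattern.csv", out / "pattern.json"


def import_patterns(csv_path, json_path=None):
    csv_path = Path(csv_path)
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    with open(json_path) as fh:
        meta = json.load(fh)
    rows = {}
    with open(csv_path) as fh:
        for row in csv.DictReader(fh):
            rows.setdefault(row["channel"], []).append(
                (int(row["sample_index"]), float(row["time_s"]), float(row["pw_us"]))
            )
    patterns = {}
    for ch, entries in rows.items():
        entries.sort()
        times = np.array([t for _, t, _ in entries])
        pw = np.array([p for _, _, p in entries])
        m = meta[ch]
        patterns[ch] = StimulationPattern(
            channel=ch, side=m["side"], muscle_group=m["muscle_group"],
            sample_times=times, pw_us=pw, amplitude_ma=m["amplitude_ma"],
            frequency_schedule=[tuple(seg) for seg in m["frequency_schedule"]],
            swing_duration=m["swing_duration"],
            provenance=m.get("provenance", {}),
        )
    return patterns
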