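"""Gait-trial analysis: filtering, step metrics, outlier rejection, ensemble
averaging, upper-extremity effort, and statistics.

Conventions: marker axes are (x, y, z) = (anterior-posterior, vertical,
medial-lateral) in meters at 100 Hz; walker handle load-cell forces are 3-D in
newtons at 1000 Hz.  Step events per side are footstrike (FS) and toe-off
(TO) with FS < TO < next FS.  Step time is FS-to-FS on a side; stance is
FS->TO, swing is TO->next FS; step length is the anterior-posterior distance
between the two heel markers at the moment of the leading foot's strike.
Upper-extremity effort (UEE) is the resultant (Euclidean norm) of the summed
left+right handle force vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

logger = logging.getLogger(__name__)

__all__ = [
    "GaitTrial",
    "StepRecord",
    "LikertResponse",
    "lowpass_zero_lag",
    "detect_step_events",
    "step_metrics",
    "reject_outlier_steps",
    "stride_normalize_and_ensemble",
    "gait_speed_estimate",
    "uee_metrics",
    "compare_conditions",
    "likert_summary",
    "ecdf_normal_distance",
]

AP, VERT, ML = 0, 1, 2  # marker axis order


@dataclass
class GaitTrial:
    """One recorded stepping trial: markers + handle forces + step events."""

    marker_time: np.ndarray  # (n,) s, 100 Hz
    marker_names: list
    marker_xyz: np.ndarray  # (n, nm, 3) m
    force_time: np.ndarray  # (nf,) s, 1000 Hz
    handle_forces: dict  # {"left": (nf, 3) N, "right": (nf, 3) N}
    events: dict  # {"left": {"footstrike": [...], "toeoff": [...]}, "right": ...}
    pattern: str = ""  # condition label, e.g. "optimized" | "manual"
    trial_id: str = ""
    walker_ml_velocity: dict = field(default_factory=dict)  # side -> per-step values
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.marker_time = np.asarray(self.marker_time, dtype=float)
        self.force_time = np.asarray(self.force_time, dtype=float)
        self.marker_xyz = np.asarray(self.marker_xyz, dtype=float)
        for t, label in ((self.marker_time, "marker"), (self.force_time, "force")):
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"{label} time must be strictly increasing")
        for side, ev in self.events.items():
            fs = np.asarray(ev.get("footstrike", []), dtype=float)
            to = np.asarray(ev.get("toeoff", []), dtype=float)
            for i in range(min(len(fs), len(to))):
                if not fs[i] < to[i]:
                    raise ValueError(f"{side}: footstrike {fs[i]} must precede toe-off {to[i]}")
                if i + 1 < len(fs) and not to[i] < fs[i + 1]:
                    raise ValueError(f"{side}: toe-off {to[i]} must precede next footstrike")

    def marker(self, name):
        return self.marker_xyz[:, self.marker_names.index(name), :]


@dataclass
class StepRecord:
    side: str
    step_time: float  # s, FS to next FS on this side
    step_length: float  # m
    swing_time: float  # s
    stance_time: float  # s
    swing_stance_ratio: float
    peak_uee: float = np.nan  # N, over the gait cycle window
    mean_uee: float = np.nan  # N
    peak_uee_swing: float = np.nan
    mean_uee_swing: float = np.nan
    ml_walker_velocity: float = np.nan  # outlier feature
    toe_travel_ap: float = np.nan  # outlier feature, m
    t_start: float = np.nan
    t_end: float = np.nan
    t_toeoff: float = np.nan
    trial_id: str = ""
    outlier_flags: list = field(default_factory=list)

    def __post_init__(self):
        if not self.step_time > 0:
            raise ValueError("step_time must be > 0")


@dataclass
class LikertResponse:
    question: int  # 1-5
    score: int  # -3..3, negative = poor outcome
    trial_id: str = ""
    condition: str = ""

    def __post_init__(self):
        if not 1 <= self.question <= 5:
            raise ValueError("question id must be 1-5")
        if not isinstance(self.score, (int, np.integer)) or not -3 <= self.score <= 3:
            raise ValueError("score must be an integer in [-3, 3]")


# ---------------------------------------------------------------- filtering --
def lowpass_zero_lag(x, fs, cutoff=6.0, order=2):
    """Zero-lag (forward-backward) Butterworth lowpass along axis 0."""
    if not fs > 2 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    b, a = sps.butter(order, cutoff, fs=fs)
    x = np.asarray(x, dtype=float)
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= padlen:
        raise ValueError(
            f"signal of length {x.shape[0]} is shorter than the filter warm-up ({padlen})"
        )
    return sps.filtfilt(b, a, x, axis=0)


# ------------------------------------------------------------------- events --
def detect_step_events(trial, heel_fraction=0.2, toe_fraction=0.25):
    """Kinematic step-event detection from foot-marker vertical positions.

    A side's foot is 'down' while its heel marker's vertical position is below
    min + heel_fraction * (max - min); footstrike is the downward crossing.
    Toe-off is the upward crossing of the toe marker through an analogous
    threshold.  Returns an events dict like GaitTrial.events.
    """
    out = {}
    t = trial.marker_time
    for side, suffix in (("left", "_L"), ("right", "_R")):
        heel = trial.marker("HEEL" + suffix)[:, VERT]
        toe = trial.marker("TOE" + suffix)[:, VERT]
        h_thr = heel.min() + heel_fraction * (heel.max() - heel.min())
        t_thr = toe.min() + toe_fraction * (toe.max() - toe.min())
        down = heel < h_thr
        fs = t[1:][~down[:-1] & down[1:]]
        up = toe > t_thr
        to = t[1:][~up[:-1] & up[1:]]
        out[side] = {"footstrike": fs.tolist(), "toeoff": to.tolist()}
    return out


# ------------------------------------------------------------- step metrics --
def _interp_marker(trial, name, when, axis):
    m = trial.marker(name)[:, axis]
    return np.interp(when, trial.marker_time, m)


def _uee_resultant(trial, combine="sum_then_norm"):
    L = np.asarray(trial.handle_forces["left"], dtype=float)
    R = np.asarray(trial.handle_forces["right"], dtype=float)
    if combine == "sum_then_norm":
        return np.linalg.norm(L + R, axis=1)
    if combine == "norm_then_sum":
        return np.linalg.norm(L, axis=1) + np.linalg.norm(R, axis=1)
    raise ValueError(f"unknown UEE combination rule {combine!r}")


def step_metrics(trial, uee_combine="sum_then_norm"):
    """Per-step spatiotemporal and UEE metrics.

    Steps missing an event are skipped with a log entry.  Returns a list of
    StepRecord (possibly empty).
    """
    records = []
    resultant = None
    if trial.handle_forces.get("left") is not None and \
            trial.handle_forces.get("right") is not None:
        resultant = _uee_resultant(trial, uee_combine)

    for side in ("left", "right"):
        ev = trial.events.get(side)
        if not ev:
            logger.info("step_metrics: no events for %s side", side)
            continue
        fs = np.asarray(ev["footstrike"], dtype=float)
        to = np.asarray(ev["toeoff"], dtype=float)
        other = "right" if side == "left" else "left"
        suffix = "_L" if side == "left" else "_R"
        other_suffix = "_R" if side == "left" else "_L"
        wv = np.asarray(trial.walker_ml_velocity.get(side, []), dtype=float)
        for i in range(len(fs) - 1):
            tos = to[(to > fs[i]) & (to < fs[i + 1])]
            if tos.size != 1:
                logger.info("step_metrics: skipping %s step %d (missing/extra toe-off)",
                            side, i)
                continue
            t0, t1, tt = fs[i], fs[i + 1], tos[0]
            step_time = t1 - t0
            stance, swing = tt - t0, t1 - tt
            try:
                heel_lead = _interp_marker(trial, "HEEL" + suffix, t1, AP)
                heel_trail = _interp_marker(trial, "HEEL" + other_suffix, t1, AP)
                step_length = heel_lead - heel_trail
                toe0 = _interp_marker(trial, "TOE" + suffix, tt, AP)
                toe1 = _interp_marker(trial, "TOE" + suffix, t1, AP)
                toe_travel = toe1 - toe0
            except ValueError:
                logger.info("step_metrics: skipping %s step %d (missing markers)", side, i)
                continue
            rec = StepRecord(
                side=side, step_time=step_time, step_length=step_length,
                swing_time=swing, stance_time=stance,
                swing_stance_ratio=swing / stance,
                toe_travel_ap=toe_travel, t_start=t0, t_end=t1, t_toeoff=tt,
                trial_id=trial.trial_id,
            )
            if i < wv.size:
                rec.ml_walker_velocity = float(wv[i])
            if resultant is not None:
                tmask = (trial.force_time >= t0) & (trial.force_time <= t1)
                smask = (trial.force_time >= tt) & (trial.force_time <= t1)
                if tmask.any():
                    rec.peak_uee = float(resultant[tmask].max())
                    rec.mean_uee = float(np.trapezoid(resultant[tmask],
                                                      trial.force_time[tmask])
                                         / (trial.force_time[tmask][-1]
                                            - trial.force_time[tmask][0]))
                if smask.sum() > 1:
                    rec.peak_uee_swing = float(resultant[smask].max())
                    rec.mean_uee_swing = float(np.trapezoid(resultant[smask],
                                                            trial.force_time[smask])
                                               / (trial.force_time[smask][-1]
                                                  - trial.force_time[smask][0]))
            records.append(rec)
    return records


# ----------------------------------------------------------------- outliers --
def reject_outlier_steps(steps, ml_velocity=None, toe_travel=None, k=1.5):
    """Tukey-fence outlier rejection on two per-step features: medial-lateral
    walker velocity and anterior-posterior toe travel.

    Features default to the fields carried by the StepRecords.  Fences
    [Q1 - k IQR, Q3 + k IQR] are computed once on the full set per feature;
    a step outside either fence is removed.  Returns (retained, log) where
    log lists (step index, feature name, value, fence).
    """
    steps = list(steps)
    if ml_velocity is None:
        ml_velocity = [s.ml_walker_velocity for s in steps]
    if toe_travel is None:
        toe_travel = [s.toe_travel_ap for s in steps]
    features = {"ml_walker_velocity": np.asarray(ml_velocity, dtype=float),
                "toe_travel_ap": np.asarray(toe_travel, dtype=float)}
    fences = {}
    for name, vals in features.items():
        ok = np.isfinite(vals)
        if ok.sum() < 4:
            logger.warning("reject_outlier_steps: <4 finite values for %s; skipped", name)
            continue
        q1, q3 = np.percentile(vals[ok], [25, 75])
        iqr = q3 - q1
        fences[name] = (q1 - k * iqr, q3 + k * iqr)
    retained, rejections = [], []
    for i, s in enumerate(steps):
        bad = False
        for name, (lo, hi) in fences.items():
            v = features[name][i]
            if np.isfinite(v) and not lo <= v <= hi:
                rejections.append((i, name, float(v), (float(lo), float(hi))))
                s.outlier_flags.append(name)
                bad = True
        if not bad:
            retained.append(s)
    return retained, rejections


# ----------------------------------------------------------------- ensemble --
def stride_normalize_and_ensemble(step_traces, n_points=101):
    """Stride-normalize joint-angle traces and ensemble average.

    step_traces: list of (time, values) pairs, one per step (each spanning
    FS to FS on its side).  Each trace is linearly resampled onto a common
    0-100 percent-gait-cycle grid; pointwise mean and sample SD are returned.
    With a single step the SD is undefined (returned as NaN, flagged).
    """
    if not step_traces:
        raise ValueError("no step traces supplied")
    grid = np.linspace(0.0, 100.0, n_points)
    resampled = []
    for t, v in step_traces:
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        pct = 100.0 * (t - t[0]) / (t[-1] - t[0])
        resampled.append(np.interp(grid, pct, v))
    resampled = np.array(resampled)
    mean = resampled.mean(axis=0)
    if len(resampled) < 2:
        logger.warning("stride ensemble: SD undefined with a single step")
        sd = np.full(n_points, np.nan)
    else:
        sd = resampled.std(axis=0, ddof=1)
    return {"percent_cycle": grid, "mean": mean, "sd": sd, "n": len(resampled)}


# --------------------------------------------------------------- gait speed --
def gait_speed_estimate(mean_step_length, mean_step_time):
    """Gait speed (m/s) from side-averaged mean step length and step time.

    Accepts scalars or per-side arrays (which are averaged first); valid when
    steps are approximately symmetric between sides.
    """
    L = float(np.mean(mean_step_length))
    T = float(np.mean(mean_step_time))
    if not T > 0:
        raise ValueError("mean step time must be > 0")
    return L / T


# ---------------------------------------------------------------------- UEE --
def uee_metrics(trial, steps=None, combine="sum_then_norm"):
    """Peak and time-averaged UEE resultant per gait cycle and per swing.

    Returns {"left": {...}, "right": {...}} with mean/SD of per-step peaks and
    time averages over the full cycle and the swing phase.
    """
    for h in ("left", "right"):
        if trial.handle_forces.get(h) is None:
            raise ValueError(f"uee_metrics: missing {h} handle force channel")
    if steps is None:
        steps = step_metrics(trial, uee_combine=combine)
    out = {}
    for side in ("left", "right"):
        recs = [s for s in steps if s.side == side]
        def agg(vals):
            vals = np.array([v for v in vals if np.isfinite(v)])
            if vals.size == 0:
                return {"mean": np.nan, "sd": np.nan, "n": 0}
            return {"mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    "n": int(vals.size)}
        out[side] = {
            "cycle_peak": agg([s.peak_uee for s in recs]),
            "cycle_mean": agg([s.mean_uee for s in recs]),
            "swing_peak": agg([s.peak_uee_swing for s in recs]),
            "swing_mean": agg([s.mean_uee_swing for s in recs]),
        }
    return out


# --------------------------------------------------------------- statistics --
def compare_conditions(a, b, kind="welch_t"):
    """Two-sample comparison.

    welch_t: unequal-variance t-test with Satterthwaite degrees of freedom.
    wilcoxon_rank_sum: Mann-Whitney/Wilcoxon rank-sum, exact when both groups
    are small (<= 20) without ties, normal approximation otherwise (scipy's
    'auto' rule).  Returns dict with statistic, p_value and extras.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind == "welch_t":
        if a.size < 2 or b.size < 2:
            raise ValueError("welch_t requires >= 2 samples per group")
        if np.var(a) == 0 and np.var(b) == 0:
            if np.isclose(a.mean(), b.mean()):
                return {"statistic": 0.0, "p_value": 1.0, "df": np.nan,
                        "note": "zero variance in both groups; equal means"}
            return {"statistic": np.nan, "p_value": np.nan, "df": np.nan,
                    "note": "zero variance in both groups; t undefined"}
        res = spstats.ttest_ind(a, b, equal_var=False)
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
                "df": float(res.df)}
    if kind == "wilcoxon_rank_sum":
        res = spstats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
    raise ValueError(f"unknown test kind {kind!r}")


def likert_summary(responses):
    """Median and interquartile range per question and condition, plus a
    rank-sum comparison across the two conditions for each question."""
    by_qc = {}
    for r in responses:
        by_qc.setdefault((r.question, r.condition), []).append(r.score)
    summary = {}
    for (q, c), scores in sorted(by_qc.items()):
        arr = np.asarray(scores, dtype=float)
        q1, q3 = np.percentile(arr, [25, 75])
        summary[(q, c)] = {"median": float(np.median(arr)), "iqr": float(q3 - q1),
                           "n": int(arr.size)}
    tests = {}
    questions = sorted({q for q, _ in by_qc})
    conditions = sorted({c for _, c in by_qc})
    if len(conditions) == 2:
        for q in questions:
            a = by_qc.get((q, conditions[0]))
            b = by_qc.get((q, conditions[1]))
            if a and b:
                tests[q] = compare_conditions(a, b, kind="wilcoxon_rank_sum")
    return {"summary": summary, "rank_sum": tests, "conditions": conditions}


def ecdf_normal_distance(x):
    """Sup distance between the sample ECDF and a fitted normal CDF — the
    graphical normality check, reported as a number (not used as a gate)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return np.nan
    cdf = spstats.norm.cdf(x, mu, sd)
    upper = np.abs(np.arange(1, n + 1) / n - cdf).max()
    lower = np.abs(cdf - np.arange(0, n) / n).max()
    return float(max(upper, lower))
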