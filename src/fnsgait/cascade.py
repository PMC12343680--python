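"""Staged optimal-control cascade.

The stimulation pattern is developed without an a-priori initial guess by a
series of OC problems: a tracking problem seeds the chain (coarse then fine
mesh), then predictive problems progressively remove the tracking terms, add
gait-shaping constraints, reduce the muscle set, increase the reserve-actuator
penalty, adjust the prescribed speed, and finally switch to the asymmetric
participant-specific muscle set over a full two-step cycle.  Each stage is
warm-started from the previous stage's solution; a stage failure halts the
cascade with earlier solutions preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .constraints import ConstraintSpec
from .costs import CostWeights
from .solver import OCSolution, SolverOptions, solve
from .transcription import OCProblem

logger = logging.getLogger(__name__)

__all__ = ["CascadeStage", "CascadeConfig", "run_cascade", "default_cascade",
           "reduced_cascade"]


@dataclass
class CascadeStage:
    """One cascade stage: a problem description plus the edits it applies
    (recorded for the audit log)."""

    name: str
    mode: str
    mesh_intervals: int
    constraints: list
    weights: CostWeights = field(default_factory=CostWeights)
    t_final: float | None = None
    active_muscles: list | None = None
    active_actuators: list | None = None
    maxiter: int | None = None
    edits: dict = field(default_factory=dict)


@dataclass
class CascadeConfig:
    """Ordered stage list; each stage's initial guess is the previous stage's
    solution (the first stage uses the midpoint-of-bounds default)."""

    stages: list
    options: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self):
        if not self.stages:
            raise ValueError("cascade needs at least one stage")


def run_cascade(model, config: CascadeConfig, reference=None):
    """Solve the stages in order with warm-start chaining.

    Returns (solutions, audit) where audit is a per-stage list of dicts
    (objective, violation, status, edits applied).  On a stage failure the
    cascade halts; solutions solved so far are returned.
    """
    solutions, audit = [], []
    guess = None
    for stage in config.stages:
        problem = OCProblem(
            model=model, mode=stage.mode, weights=stage.weights,
            constraints=stage.constraints, mesh_intervals=stage.mesh_intervals,
            reference=reference if stage.mode == "tracking" else reference,
            t_final=stage.t_final, active_muscles=stage.active_muscles,
            active_actuators=stage.active_actuators, name=stage.name,
        )
        opts = config.options
        if stage.maxiter is not None:
            opts = replace(opts, maxiter=stage.maxiter)
        sol = solve(problem, options=opts, initial_guess=guess)
        solutions.append(sol)
        audit.append({
            "stage": stage.name, "edits": dict(stage.edits),
            "objective": sol.objective, "status": sol.status,
            "constraint_violation": sol.constraint_violation,
            "initial_violation": sol.initial_violation,
            "violation_report": sol.violation_report,
            "iterations": sol.iterations, "solve_time": sol.solve_time,
            "cost_report": sol.cost_report,
        })
        if not sol.success:
            logger.warning("cascade halted at stage %s (status=%s, violation=%.3g)",
                           stage.name, sol.status, sol.constraint_violation)
            break
        guess = sol.trajectory
    return solutions, audit


# ------------------------------------------------------- stage construction --
def _symmetric_muscles(model):
    names = set(model.muscle_names)
    out = []
    for n in model.muscle_names:
        if n.endswith("_l") and n[:-2] + "_r" in names:
            out.append(n)
        elif n.endswith("_r") and n[:-2] + "_l" in names:
            out.append(n)
        elif "_l_" in n and n.replace("_l_", "_r_") in names:
            out.append(n)
        elif "_r_" in n and n.replace("_r_", "_l_") in names:
            out.append(n)
    return out


def default_cascade(model, reference, mesh_fine=50, mesh_coarse=10,
                    weights=None, predict4_penalty_factor=10.0,
                    stages="all", maxiter=1000):
    """The standard stage sequence.

    stages="all": NTtrack(coarse) -> NTtrack(fine) -> Predict1..Predict6.
    stages="reduced": NTtrack(coarse) -> Predict1 -> Predict2, all at the
    coarse mesh (the desk-scale property check).
    """
    w = weights or CostWeights()
    sym_set = _symmetric_muscles(model)
    track_tf = reference.meta.get("stride_time", 1.0) / 2.0

    def track_stage(name, mesh):
        return CascadeStage(
            name=name, mode="tracking", mesh_intervals=mesh,
            constraints=[
                ConstraintSpec("sym_half"),
                ConstraintSpec("speed_bound", {"percent": 0.10}),
            ],
            weights=w, t_final=track_tf, active_muscles=sym_set,
            edits={"mesh": mesh, "speed_bound_percent": 10,
                   "tracking": True, "t_final": track_tf},
        )

    base_predict = [
        ConstraintSpec("sym_half"),
        ConstraintSpec("speed_bound", {"percent": 1.0}),
        ConstraintSpec("intersect"),
        ConstraintSpec("rest"),
    ]

    def predict_stage(name, mesh, avg_speed, tf_bounds, extra=(), weights_=None,
                      muscles=None, sym="sym_half", edits=None):
        cons = [ConstraintSpec(sym),
                ConstraintSpec("speed_bound", {"percent": 1.0}),
                ConstraintSpec("intersect"), ConstraintSpec("rest"),
                ConstraintSpec("avg_speed", {"target": avg_speed}),
                ConstraintSpec("tf_bound", {"bounds": tf_bounds})]
        cons += list(extra)
        return CascadeStage(
            name=name, mode="predictive", mesh_intervals=mesh,
            constraints=cons, weights=weights_ or w,
            active_muscles=muscles if muscles is not None else sym_set,
            edits=edits or {},
        )

    mesh = mesh_fine if stages == "all" else mesh_coarse
    p1 = predict_stage(
        "Predict1", mesh, 0.4, (0.4, 0.6),
        edits={"drop_tracking": True, "add": ["intersect", "rest", "avg_speed=0.4",
                                              "tf=[0.4,0.6]"],
               "speed_bound_percent": 100})
    p2 = predict_stage(
        "Predict2", mesh, 0.4, (0.4, 0.6), extra=[ConstraintSpec("knees")],
        edits={"add": ["knees"]})
    # A stage counts as converged at the cascade's documented dynamic-
    # consistency target (1e-4 in scaled state units); the feasibility
    # polish typically lands well below it.
    opts = SolverOptions(maxiter=maxiter, feasibility_tol=1e-4)
    if stages == "reduced":
        return CascadeConfig(
            stages=[track_stage("NTtrack10", mesh_coarse), p1, p2],
            options=opts,
        )

    p3 = predict_stage(
        "Predict3", mesh, 0.1, (0.9, 1.1), extra=[ConstraintSpec("knees")],
        muscles=sym_set,
        edits={"muscles": "symmetric iliopsoas/vasti/tibialis-anterior set",
               "avg_speed": 0.1, "tf": [0.9, 1.1], "actuators": "full set"})
    w4 = replace(w, reserve_penalty=w.reserve_penalty * predict4_penalty_factor)
    p4 = predict_stage(
        "Predict4", mesh, 0.1, (0.9, 1.1), extra=[ConstraintSpec("knees")],
        weights_=w4, edits={"reserve_penalty": w4.reserve_penalty})
    p5 = predict_stage(
        "Predict5", mesh, 0.2, (0.9, 1.1), extra=[ConstraintSpec("knees")],
        weights_=w4, edits={"avg_speed": 0.2})
    p6 = predict_stage(
        "Predict6", mesh, 0.2, (2.0, 2.2), extra=[ConstraintSpec("knees")],
        weights_=w4, muscles=list(model.muscle_names), sym="sym_full",
        edits={"model": "participant-specific asymmetric muscle set",
               "symmetry": "full stride", "tf": [2.0, 2.2]})
    return CascadeConfig(
        stages=[track_stage("NTtrack10", mesh_coarse),
                track_stage("NTtrack50", mesh_fine), p1, p2, p3, p4, p5, p6],
        options=opts,
    )


REDUCED_STAGE_MAXITER = {"NTtrack10": 3000, "Predict1": 2000, "Predict2": 1500}


def reduced_cascade(model, reference, mesh=10, maxiter=None):
    """NTtrack -> Predict1 -> Predict2 at a coarse mesh.

    Per-stage iteration budgets default to the values that solve the planar
    fixture on a single workstation core (the cold-started tracking stage
    needs the most).
    """
    cfg = default_cascade(model, reference, mesh_coarse=mesh, stages="reduced",
                          maxiter=maxiter or 1000)
    if maxiter is None:
        for st in cfg.stages:
            st.maxiter = REDUCED_STAGE_MAXITER.get(st.name, 1500)
    return cfg
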