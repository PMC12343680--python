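"""NLP solution of transcribed optimal-control problems.

The scaled NLP is handed to scipy's interior/trust-region constrained
optimizer (``trust-constr``); constraint Jacobians use the transcription's
sparsity pattern with grouped finite differences, the objective gradient
combines a colored Jacobian of the per-point cost densities with analytic
final-time and travel-distance terms.  Solutions report the objective, a
per-subterm cost breakdown, the raw constraint violation per family, and the
solver status; failures (iteration limit, infeasible) are reported with the
last iterate, never raised.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

from . import costs as costs_mod
from .trajectory import EXCITATION_HI, EXCITATION_LO, Trajectory
from .transcription import ColoredJacobian, OCProblem, Transcription, transcribe

logger = logging.getLogger(__name__)

__all__ = ["SolverOptions", "OCSolution", "solve", "midpoint_guess"]


@dataclass
class SolverOptions:
    maxiter: int = 1000
    gtol: float = 1.0e-4  # first-order optimality
    xtol: float = 1.0e-10
    feasibility_tol: float = 1.0e-6  # success threshold on raw violation
    fd_step: float = 1.0e-6
    verbose: int = 0


@dataclass
class OCSolution:
    trajectory: Trajectory
    objective: float
    status: str  # "success" | "max_iterations" | "infeasible" | "failed"
    success: bool
    constraint_violation: float
    violation_report: dict
    iterations: int
    message: str
    cost_report: dict = field(default_factory=dict)
    name: str = "ocp"
    solve_time: float = 0.0
    initial_violation: float = np.nan  # raw violation of the initial guess
    edits: dict = field(default_factory=dict)


def midpoint_guess(tr: Transcription):
    """The default initial guess: the midpoint of every variable's bounds."""
    return 0.5 * (tr.lb + tr.ub)


def guess_from_trajectory(tr: Transcription, traj: Trajectory):
    """Warm start: resample a previous solution onto the new point grid,
    mapping channels by name (new channels start at their bound midpoint)."""
    z = midpoint_guess(tr)
    tf = float(np.clip(traj.duration, tr.lb[tr.i_tf], tr.ub[tr.i_tf]))
    z[tr.i_tf] = tf
    # Resample in normalized time so duration changes stretch the motion.
    src_tau = (traj.time - traj.t_i) / traj.duration
    model = tr.model

    def interp(col):
        return np.interp(tr.tau, src_tau, col)

    ci = {n: j for j, n in enumerate(traj.coord_names)}
    mi = {n: j for j, n in enumerate(traj.muscle_names)}
    ai = {n: j for j, n in enumerate(traj.actuator_names)}
    for jq, name in enumerate(model.coord_names):
        if name in ci:
            qcol = interp(traj.q[:, ci[name]])
            ucol = interp(traj.u[:, ci[name]])
            for s in range(tr.P):
                z[tr.q_idx(s)[jq]] = qcol[s]
                z[tr.u_idx(s)[jq]] = ucol[s]
    for jm, mus_idx in enumerate(tr.mus_active_idx):
        name = model.muscle_names[mus_idx]
        if name in mi:
            acol = interp(traj.a[:, mi[name]])
            ecol = interp(traj.excitation[:, mi[name]])
            for s in range(tr.P):
                z[tr.a_idx(s)[jm]] = acol[s]
                z[tr.e_idx(s)[jm]] = ecol[s]
    for ja, act_idx in enumerate(tr.act_active_idx):
        name = model.actuator_names[act_idx]
        if name in ai:
            rcol = interp(traj.actuator[:, ai[name]])
            for s in range(tr.P):
                z[tr.r_idx(s)[ja]] = rcol[s]
    return np.clip(z, tr.lb, tr.ub)


def trajectory_from_z(tr: Transcription, z):
    Q, U, Aact, Eact, Ract, tf = tr.unpack(z)
    model = tr.model
    mus_names = [model.muscle_names[i] for i in tr.mus_active_idx]
    act_names = [model.actuator_names[i] for i in tr.act_active_idx]
    return Trajectory(
        tr.tau * tf, list(model.coord_names), mus_names, act_names,
        Q, U, np.clip(Aact, 0.0, 1.0),
        np.clip(Eact, EXCITATION_LO, EXCITATION_HI),
        np.clip(Ract, -1.0, 1.0), model=model,
        meta={"name": tr.problem.name, "mode": tr.problem.mode},
    )


def _objective_machinery(tr: Transcription):
    P, npp = tr.P, tr.npp
    S = sparse.lil_matrix((2 * P, tr.n_vars), dtype=bool)
    for s in range(P):
        cols = np.arange(s * npp, (s + 1) * npp)
        S[s, cols] = True
        S[P + s, cols] = True
    S = S.tocsc()

    def density_fun(z):
        main, eff = tr.per_point_costs(z)
        return np.concatenate([main, eff])

    jac = ColoredJacobian(density_fun, S, step=1e-7,
                          fun_multi=tr.per_point_costs_multi)

    def com_travel_grad(z):
        g = np.zeros(tr.n_vars)
        h = 1e-6
        for s, sign in ((0, -1.0), (tr.P - 1, 1.0)):
            qi = tr.q_idx(s)
            Q0 = z[qi]
            batch = np.repeat(Q0[None, :], tr.nq + 1, axis=0)
            batch[1:] += np.eye(tr.nq) * h
            com = tr.model.com_position(batch)[:, 0]
            g[qi] = sign * (com[1:] - com[0]) / h
        return g

    def grad(z):
        tf = z[-1]
        dens0 = density_fun(z)
        main0, eff0 = dens0[:P], dens0[P:]
        J_main = tf * float(tr.wq_tau @ main0)
        J_eff = tf * float(tr.wq_tau @ eff0)
        Jg = jac(z, f0=dens0)
        gmain = tf * np.asarray(Jg[:P].T @ tr.wq_tau).ravel()
        geff = tf * np.asarray(Jg[P:].T @ tr.wq_tau).ravel()
        d = tr.com_travel(z)
        dd = com_travel_grad(z)
        if tr.problem.mode == "tracking":
            g = gmain + d * geff + J_eff * dd
            g[-1] += (J_main + d * J_eff) / tf
        elif not tr.problem.divide_effort_by_distance:
            g = gmain + geff
            g[-1] += (J_main + J_eff) / tf
        else:
            d_eff, slope = tr.smooth_travel(d)
            g = gmain + geff / d_eff - (J_eff / d_eff**2) * slope * dd
            g[-1] += (J_main + J_eff / d_eff) / tf
        return g

    return grad


def _feasibility_polish(tr, zs, lbs, ubs, con_s, con_jac, options,
                        max_steps=6):
    """Gauss-Newton feasibility restoration on the constraint residuals.

    The trust-region solver often stops with a small residual infeasibility
    (1e-4-ish) at its iteration limit; a few damped sparse least-squares
    steps on c(z) project the iterate onto the constraint manifold with a
    negligible objective change.  Bounds are enforced by clipping; steps
    that fail to reduce the violation are rejected.
    """
    from scipy.sparse.linalg import lsqr

    def violation(c):
        v = np.maximum(tr.clb - c, 0) + np.maximum(c - tr.cub, 0)
        return v, float(v.max()) if v.size else 0.0

    free = (ubs - lbs) > 1e-12  # pinned variables cannot absorb residuals
    c = con_s(zs)
    _, best = violation(c)
    for _ in range(max_steps):
        if best <= 0.1 * options.feasibility_tol:
            break
        J = con_jac(zs, f0=c)
        resid = c - np.clip(c, tr.clb, tr.cub)
        dz = np.zeros_like(zs)
        dz[free] = lsqr(J[:, free], -resid, damp=1e-8, atol=1e-12, btol=1e-12,
                        iter_lim=400)[0]
        step = 1.0
        accepted = False
        for _ in range(4):
            z_try = np.clip(zs + step * dz, lbs, ubs)
            c_try = con_s(z_try)
            _, v_try = violation(c_try)
            if v_try < best:
                zs, c, best = z_try, c_try, v_try
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return zs


def solve(problem: OCProblem, options: SolverOptions | None = None,
          initial_guess=None) -> OCSolution:
    """Transcribe and solve; deterministic for identical guess and options."""
    options = options or SolverOptions()
    tr = transcribe(problem)

    if initial_guess is None:
        initial_guess = problem.initial_guess
    if initial_guess is None:
        z0 = midpoint_guess(tr)
    elif isinstance(initial_guess, Trajectory):
        z0 = guess_from_trajectory(tr, initial_guess)
    else:
        z0 = np.asarray(initial_guess, dtype=float)

    zs0 = tr.to_scaled(z0)
    lbs = tr.to_scaled(tr.lb)
    ubs = tr.to_scaled(tr.ub)
    zs0 = np.clip(zs0, lbs, ubs)

    grad_phys = _objective_machinery(tr)

    def obj_s(zs):
        return tr.objective(tr.to_physical(zs))

    def grad_s(zs):
        return grad_phys(tr.to_physical(zs)) * tr.scale

    def con_s(zs):
        return tr.constraint_fun(tr.to_physical(zs))

    def con_s_multi(Zs):
        return tr.constraint_fun_multi(tr.center[None, :] + tr.scale[None, :] * Zs)

    con_jac = ColoredJacobian(con_s, tr.sparsity, step=options.fd_step,
                              fun_multi=con_s_multi)
    nlc = optimize.NonlinearConstraint(con_s, tr.clb, tr.cub, jac=con_jac)

    initial_violation, _ = tr.raw_violation(tr.to_physical(zs0))

    t0 = time.perf_counter()
    # Warm starts carried over from a different stage usually violate the new
    # stage's constraints; projecting them onto the constraint manifold first
    # saves the trust-region method its slow feasibility phase.
    if initial_violation > 10 * options.feasibility_tol and \
            isinstance(initial_guess, Trajectory):
        zs0 = _feasibility_polish(tr, zs0, lbs, ubs, con_s, con_jac, options,
                                  max_steps=8)
    res = optimize.minimize(
        obj_s, zs0, jac=grad_s, method="trust-constr",
        bounds=optimize.Bounds(lbs, ubs),
        constraints=[nlc],
        options={
            "maxiter": options.maxiter, "gtol": options.gtol,
            "xtol": options.xtol, "verbose": options.verbose,
        },
    )

    zs = np.clip(res.x, lbs, ubs)
    zs = _feasibility_polish(tr, zs, lbs, ubs, con_s, con_jac, options)
    elapsed = time.perf_counter() - t0

    z = tr.to_physical(zs)
    violation, vreport = tr.raw_violation(z)
    if violation <= options.feasibility_tol:
        status, ok = "success", True
    elif res.status == 0 or res.niter >= options.maxiter:
        status, ok = "max_iterations", False
    else:
        status, ok = "infeasible", False

    traj = trajectory_from_z(tr, z)
    report = _cost_report(tr, traj, z)
    logger.info("%s: status=%s obj=%.6g viol=%.3g iters=%d (%.1f s)",
                problem.name, status, res.fun, violation, res.niter, elapsed)
    return OCSolution(
        trajectory=traj, objective=float(res.fun), status=status, success=ok,
        constraint_violation=violation, violation_report=vreport,
        iterations=int(res.niter), message=str(res.message),
        cost_report=report, name=problem.name, solve_time=elapsed,
        initial_violation=initial_violation,
    )


def _cost_report(tr: Transcription, traj: Trajectory, z):
    """Per-subterm cost report computed through the costs module (shared
    quadrature, so it matches the transcription objective)."""
    p = tr.problem
    w = p.weights
    sub = {}
    sub["J_s"] = costs_mod.eval_synergy(traj, tr.model.muscle_groups)
    d = tr.com_travel(z)
    if p.mode == "predictive" and p.divide_effort_by_distance:
        sub["J_e"] = costs_mod.eval_effort(traj, w, com_distance=tr.smooth_travel(d)[0],
                                           divide_by_distance=True, model=tr.model)
    else:
        sub["J_e"] = costs_mod.eval_effort(traj, w, model=tr.model)
    sub["J_p"] = costs_mod.eval_energy_penalty(traj)
    sub["J_ad"] = costs_mod.eval_aux_deriv(traj)
    if p.mode == "tracking":
        sub["J_mt"] = costs_mod.eval_marker_tracking(traj, p.reference, p.marker_set,
                                                     model=tr.model)
        sub["J_ct"] = costs_mod.eval_contact_tracking(traj, p.reference, model=tr.model)
        return costs_mod.cost_report(sub, w, "tracking", d=max(d, 1e-6))
    return costs_mod.cost_report(sub, w, "predictive", d=d)
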