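"""Direct-collocation transcription of an optimal-control problem.

Hermite-Simpson (separated) collocation: states and controls are decision
variables at mesh nodes and interval midpoints; interval defects enforce the
implicit model dynamics, and the free final time (when a tf_bound constraint
is present) is an extra decision variable.  The transcription produces plain
callables plus a boolean Jacobian sparsity pattern; derivatives are obtained
by grouped finite differences (greedy column coloring), which keeps the cost
of one Jacobian at a small multiple of one batched dynamics evaluation.

Several constraint families reduce to simple variable bounds and are applied
that way: joint-speed bounds (every point), initial rest (point 0 speeds),
straight knees at the cycle endpoints (which are the double-stance onsets for
the half/full stride cycles solved here), and the final-time box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .constraints import (
    DEFAULT_KNEE_TOLERANCE,
    DEFAULT_MIN_GAP,
    ConstraintSpec,
    default_full_exemptions,
    default_half_exemptions,
)
from .costs import CostWeights, MarkerSet
from .trajectory import EXCITATION_HI, EXCITATION_LO, Trajectory

__all__ = ["OCProblem", "Transcription", "transcribe"]


@dataclass
class OCProblem:
    """Declarative OC problem: model + cost composition + constraints + mesh."""

    model: object
    mode: str  # "tracking" | "predictive"
    weights: CostWeights = field(default_factory=CostWeights)
    constraints: list = field(default_factory=list)
    mesh_intervals: int = 10
    reference: object = None  # ReferenceData, required for tracking
    marker_set: object = None  # MarkerSet; default derived from the model
    t_final: float | None = None  # fixed final time (s) if no tf_bound constraint
    active_muscles: list | None = None  # names; default all
    active_actuators: list | None = None  # names; default all
    initial_guess: object = None  # Trajectory | None -> midpoint of bounds
    divide_effort_by_distance: bool = True
    # predictive effort is normalized per meter of CoM travel; disable for
    # non-locomoting problems (oracle fixtures, postural holds)
    point_bounds: dict = field(default_factory=dict)
    # extra endpoint variable bounds: {"start"|"end": {"q/name"|"u/name"|...:
    #   (lo, hi)}} — used for boundary conditions such as rest-to-rest targets
    name: str = "ocp"

    def __post_init__(self):
        if self.mode not in ("tracking", "predictive"):
            raise ValueError(f"unknown OC mode {self.mode!r}")
        if self.mesh_intervals < 2:
            raise ValueError("mesh_intervals must be >= 2")
        if self.mode == "tracking" and self.reference is None:
            raise ValueError("tracking mode requires ReferenceData")
        if self.marker_set is None and self.mode == "tracking":
            self.marker_set = MarkerSet.from_model(self.model)
        if self.active_muscles is None:
            self.active_muscles = list(self.model.muscle_names)
        if self.active_actuators is None:
            self.active_actuators = list(self.model.actuator_names)
        kinds = [c.kind for c in self.constraints]
        if "tf_bound" not in kinds and self.t_final is None:
            raise ValueError("either a tf_bound constraint or a fixed t_final is required")
        if self.mode == "tracking" and self.t_final is None:
            raise ValueError("tracking mode requires a fixed t_final (the reference span)")

    def constraint(self, kind):
        for c in self.constraints:
            if c.kind == kind:
                return c
        return None


def _greedy_coloring(S):
    """Column groups such that no two columns in a group share a row.

    S: scipy.sparse bool matrix (rows x cols).  Returns an int array of group
    ids per column.
    """
    S = sparse.csc_matrix(S)
    n_rows, n_cols = S.shape
    colors = np.full(n_cols, -1, dtype=int)
    occupied = []  # per color: bool row mask
    for c in range(n_cols):
        rows = S.indices[S.indptr[c]:S.indptr[c + 1]]
        for k, occ in enumerate(occupied):
            if not occ[rows].any():
                colors[c] = k
                occ[rows] = True
                break
        else:
            occ = np.zeros(n_rows, dtype=bool)
            occ[rows] = True
            occupied.append(occ)
            colors[c] = len(occupied) - 1
    return colors


class ColoredJacobian:
    """Finite-difference Jacobian with column grouping on a fixed sparsity.

    With ``fun_multi`` (a stacked evaluator mapping (K, n) -> (K, m)) every
    color's perturbed point is evaluated in a single batched call, so one
    Jacobian costs little more than one large dynamics evaluation.
    """

    def __init__(self, fun, sparsity, step=1e-6, fun_multi=None):
        self.fun = fun
        self.fun_multi = fun_multi
        self.S = sparse.csc_matrix(sparsity)
        self.colors = _greedy_coloring(self.S)
        self.n_colors = self.colors.max() + 1
        self.step = step

    def __call__(self, z, f0=None):
        if f0 is None:
            f0 = self.fun(z)
        n_rows, n_cols = self.S.shape
        Zp = np.repeat(z[None, :], self.n_colors, axis=0)
        for color in range(self.n_colors):
            Zp[color, self.colors == color] += self.step
        if self.fun_multi is not None:
            F1 = self.fun_multi(Zp)
        else:
            F1 = np.stack([self.fun(Zp[k]) for k in range(self.n_colors)])
        dF = (F1 - f0[None, :]) / self.step
        data, rows, cols = [], [], []
        for c in range(n_cols):
            r = self.S.indices[self.S.indptr[c]:self.S.indptr[c + 1]]
            rows.append(r)
            cols.append(np.full(r.size, c))
            data.append(dF[self.colors[c], r])
        return sparse.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_rows, n_cols),
        )


class Transcription:
    """NLP realization of an OCProblem (scaled variables, sparse Jacobians)."""

    def __init__(self, problem: OCProblem):
        self.problem = problem
        model = problem.model
        self.model = model
        N = problem.mesh_intervals
        self.N = N
        self.P = 2 * N + 1  # collocation points (nodes + midpoints)

        self.mus_active_idx = np.array(
            [model.muscle_index[m] for m in problem.active_muscles], dtype=int
        )
        self.act_active_idx = np.array(
            [model.actuator_names.index(a) for a in problem.active_actuators], dtype=int
        )
        self.mus_mask = np.zeros(model.n_mus)
        self.mus_mask[self.mus_active_idx] = 1.0
        nq, nm, na = model.n_q, len(self.mus_active_idx), len(self.act_active_idx)
        self.nq, self.nm, self.na = nq, nm, na
        self.nx = 2 * nq + nm
        self.npp = 2 * nq + 2 * nm + na  # variables per collocation point
        self.n_vars = self.P * self.npp + 1  # + free final time
        self.i_tf = self.n_vars - 1

        self.tau = np.arange(self.P) / (self.P - 1)  # normalized time grid
        # Composite-Simpson quadrature over node/midpoint pattern: exactly the
        # integral implied by the Hermite-Simpson transcription, so the
        # discrete optimum of a smooth problem matches the continuous one.
        dtau = 1.0 / (self.P - 1)
        wq = np.full(self.P, 2.0)
        wq[1::2] = 4.0
        wq[0] = wq[-1] = 1.0
        self.wq_tau = wq * dtau / 3.0

        self._build_bounds()
        self._build_scaling()
        self._build_constraint_layout()
        self._build_objective_terms()

    # ------------------------------------------------------------ variables
    def idx(self, s, offset, count):
        base = s * self.npp + offset
        return np.arange(base, base + count)

    def q_idx(self, s):
        return self.idx(s, 0, self.nq)

    def u_idx(self, s):
        return self.idx(s, self.nq, self.nq)

    def a_idx(self, s):
        return self.idx(s, 2 * self.nq, self.nm)

    def e_idx(self, s):
        return self.idx(s, 2 * self.nq + self.nm, self.nm)

    def r_idx(self, s):
        return self.idx(s, 2 * self.nq + 2 * self.nm, self.na)

    def _build_bounds(self):
        p, model = self.problem, self.model
        lb = np.empty(self.n_vars)
        ub = np.empty(self.n_vars)

        # Speed bounds: percentage of reference ranges when declared,
        # otherwise each coordinate's default speed range.
        sb = p.constraint("speed_bound")
        speed_rng = {c.name: c.default_speed_range for c in model.coords}
        if sb is not None:
            ranges = sb.parameters.get("nt_speed_ranges")
            if ranges is None and p.reference is not None:
                ranges = p.reference.nt_speed_ranges
            if not ranges:
                raise ValueError("speed_bound constraint: no reference speed ranges available")
            from .constraints import speed_bounds as _sb
            scaled = _sb(ranges, sb.parameters["percent"])
            for name, (lo, hi) in scaled.items():
                if hi - lo < 1e-9:  # degenerate reference range: keep default
                    continue
                dlo, dhi = speed_rng.get(name, (lo, hi))
                speed_rng[name] = (max(lo, dlo), min(hi, dhi))

        q_lo = np.array([c.range[0] for c in model.coords])
        q_hi = np.array([c.range[1] for c in model.coords])
        u_lo = np.array([speed_rng[c.name][0] for c in model.coords])
        u_hi = np.array([speed_rng[c.name][1] for c in model.coords])
        for s in range(self.P):
            lb[self.q_idx(s)], ub[self.q_idx(s)] = q_lo, q_hi
            lb[self.u_idx(s)], ub[self.u_idx(s)] = u_lo, u_hi
            lb[self.a_idx(s)], ub[self.a_idx(s)] = 0.0, 1.0
            lb[self.e_idx(s)], ub[self.e_idx(s)] = EXCITATION_LO, EXCITATION_HI
            lb[self.r_idx(s)], ub[self.r_idx(s)] = -1.0, 1.0

        # Initial rest: all point-0 speeds pinned to zero.
        if p.constraint("rest") is not None:
            lb[self.u_idx(0)] = ub[self.u_idx(0)] = 0.0

        # Straight knees at the cycle endpoints (double-stance onsets).
        ck = p.constraint("knees")
        if ck is not None:
            tol = ck.parameters.get("tolerance", DEFAULT_KNEE_TOLERANCE)
            knee_cols = [i for i, n in enumerate(model.coord_names) if n.startswith("knee")]
            for s in (0, self.P - 1):
                qi = self.q_idx(s)
                for j in knee_cols:
                    lb[qi[j]] = max(lb[qi[j]], -tol)
                    ub[qi[j]] = min(ub[qi[j]], tol)

        # User-supplied endpoint boundary conditions.
        block_of = {"q": self.q_idx, "u": self.u_idx, "a": self.a_idx,
                    "e": self.e_idx, "r": self.r_idx}
        names_of = {
            "q": model.coord_names, "u": model.coord_names,
            "a": [model.muscle_names[i] for i in self.mus_active_idx],
            "e": [model.muscle_names[i] for i in self.mus_active_idx],
            "r": [model.actuator_names[i] for i in self.act_active_idx],
        }
        for where, entries in p.point_bounds.items():
            s = 0 if where == "start" else self.P - 1
            for label, (lo, hi) in entries.items():
                block, nm = label.split("/", 1)
                j = names_of[block].index(nm)
                i = block_of[block](s)[j]
                lb[i], ub[i] = lo, hi

        ct = p.constraint("tf_bound")
        if ct is not None:
            lo, hi = ct.parameters["bounds"]
            lb[self.i_tf], ub[self.i_tf] = lo, hi
        else:
            lb[self.i_tf] = ub[self.i_tf] = p.t_final

        if np.any(lb > ub + 1e-12):
            bad = int(np.argmax(lb - ub))
            raise ValueError(
                f"inconsistent variable bounds at index {bad}: "
                f"lower {lb[bad]} > upper {ub[bad]}"
            )
        self.lb, self.ub = lb, ub

    def _build_scaling(self):
        # Per-kind affine scaling to O(1); pinned variables get the kind scale.
        model = self.model
        scale = np.empty(self.n_vars)
        center = np.empty(self.n_vars)
        q_rng = np.array([c.range for c in model.coords])
        for s in range(self.P):
            qi = self.q_idx(s)
            center[qi] = q_rng.mean(axis=1)
            scale[qi] = np.maximum((q_rng[:, 1] - q_rng[:, 0]) / 2, 0.05)
            ui = self.u_idx(s)
            center[ui] = 0.0
            scale[ui] = np.maximum(np.abs([self.lb[ui], self.ub[ui]]).max(axis=0), 0.5)
            ai, ei, ri = self.a_idx(s), self.e_idx(s), self.r_idx(s)
            center[ai], scale[ai] = 0.5, 0.5
            center[ei], scale[ei] = 0.5, 0.5
            center[ri], scale[ri] = 0.0, 1.0
        center[self.i_tf] = 0.5 * (self.lb[self.i_tf] + self.ub[self.i_tf])
        scale[self.i_tf] = max(0.5 * (self.ub[self.i_tf] - self.lb[self.i_tf]), 0.1)
        self.scale, self.center = scale, center
        # State scale for defect rows (q, u, a blocks).  Speeds use each
        # coordinate's physical default range, not any stage-tightened bound,
        # so defect units do not change across cascade stages.
        u_scale = np.array([
            max(abs(c.default_speed_range[0]), abs(c.default_speed_range[1])) / 2
            for c in model.coords
        ])
        self.x_scale = np.concatenate([scale[self.q_idx(0)], u_scale, np.full(self.nm, 0.5)])

    def to_scaled(self, z):
        return (z - self.center) / self.scale

    def to_physical(self, zs):
        return self.center + self.scale * zs

    # ------------------------------------------------------- dynamics eval
    def unpack(self, z):
        Z = z[:-1].reshape(self.P, self.npp)
        Q = Z[:, :self.nq]
        U = Z[:, self.nq:2 * self.nq]
        Aact = Z[:, 2 * self.nq:2 * self.nq + self.nm]
        Eact = Z[:, 2 * self.nq + self.nm:2 * self.nq + 2 * self.nm]
        Ract = Z[:, 2 * self.nq + 2 * self.nm:]
        return Q, U, Aact, Eact, Ract, z[-1]

    def _full_mus(self, arr_active, fill):
        full = np.full((arr_active.shape[0], self.model.n_mus), fill)
        full[:, self.mus_active_idx] = arr_active
        return full

    def _full_act(self, arr_active):
        full = np.zeros((arr_active.shape[0], self.model.n_act))
        full[:, self.act_active_idx] = arr_active
        return full

    def state_derivatives(self, Q, U, Aact, Eact, Ract):
        A = self._full_mus(Aact, 0.0)
        E = self._full_mus(Eact, EXCITATION_LO)
        R = self._full_act(Ract)
        Udot, Adot = self.model.forward_dynamics(
            Q, U, A, E, R, active_muscles=self.mus_mask
        )
        return np.concatenate([U, Udot, Adot[:, self.mus_active_idx]], axis=1)

    def states(self, Q, U, Aact):
        return np.concatenate([Q, U, Aact], axis=1)

    # ----------------------------------------------------- constraint rows
    def _build_constraint_layout(self):
        p = self.problem
        rows = []
        self.n_defect_rows = 2 * self.N * self.nx
        rows.append(("defects", self.n_defect_rows))

        self.has_sym = False
        for kind in ("sym_half", "sym_full"):
            c = p.constraint(kind)
            if c is not None:
                self._prepare_symmetry(c)
                self.has_sym = True
                rows.append((kind, len(self.sym_keep)))
                break

        self.avg_speed_target = None
        c = p.constraint("avg_speed")
        if c is not None:
            self.avg_speed_target = float(c.parameters["target"])
            rows.append(("avg_speed", 1))

        self.min_gap = None
        c = p.constraint("intersect")
        if c is not None:
            self.min_gap = float(c.parameters.get("min_gap", DEFAULT_MIN_GAP))
            rows.append(("intersect", self.P))

        self.row_layout = rows
        self.n_rows = sum(n for _, n in rows)

        clb = np.zeros(self.n_rows)
        cub = np.zeros(self.n_rows)
        if self.min_gap is not None:
            off = self.n_rows - self.P
            cub[off:] = np.inf
        self.clb, self.cub = clb, cub

        # Sparsity pattern.
        S = sparse.lil_matrix((self.n_rows, self.n_vars), dtype=bool)
        row = 0
        point_cols = lambda s: np.arange(s * self.npp, (s + 1) * self.npp)
        for k in range(self.N):
            cols = np.concatenate([point_cols(2 * k), point_cols(2 * k + 1),
                                   point_cols(2 * k + 2), [self.i_tf]])
            S[row:row + 2 * self.nx, cols] = True
            row += 2 * self.nx
        for name, n in self.row_layout[1:]:
            if name in ("sym_half", "sym_full"):
                cols = np.concatenate([point_cols(0), point_cols(self.P - 1)])
                S[row:row + n, cols] = True
                row += n
            elif name == "avg_speed":
                cols = np.concatenate([self.q_idx(0), self.q_idx(self.P - 1), [self.i_tf]])
                S[row, cols] = True
                row += 1
            elif name == "intersect":
                for s in range(self.P):
                    S[row + s, self.q_idx(s)] = True
                row += self.P
        self.sparsity = S.tocsc()

    def _prepare_symmetry(self, cspec):
        """Precompute (keep, perm) index arrays into the per-point layout."""
        model = self.model
        mode = "half" if cspec.kind == "sym_half" else "full"
        self.sym_mode = mode
        exemptions = cspec.parameters.get("exemptions")
        if exemptions is None:
            exemptions = (default_half_exemptions(model) if mode == "half"
                          else default_full_exemptions(model))
        import fnmatch

        def exempt(lb):
            return any(fnmatch.fnmatch(lb, pat) for pat in exemptions)

        coord_names = model.coord_names
        mus_names = [model.muscle_names[i] for i in self.mus_active_idx]
        act_names = [model.actuator_names[i] for i in self.act_active_idx]
        labels = ([f"q/{n}" for n in coord_names] + [f"u/{n}" for n in coord_names]
                  + [f"a/{n}" for n in mus_names] + [f"e/{n}" for n in mus_names]
                  + [f"r/{n}" for n in act_names])

        def twin(nm):
            if nm.endswith("_l"):
                return nm[:-2] + "_r"
            if nm.endswith("_r"):
                return nm[:-2] + "_l"
            if "_l_" in nm:
                return nm.replace("_l_", "_r_")
            if "_r_" in nm:
                return nm.replace("_r_", "_l_")
            return nm

        if mode == "full":
            perm = np.arange(len(labels))
        else:
            perm = []
            for block, names in (("q", coord_names), ("u", coord_names),
                                 ("a", mus_names), ("e", mus_names), ("r", act_names)):
                index = {n: i for i, n in enumerate(names)}
                base = {"q": 0, "u": len(coord_names), "a": 2 * len(coord_names),
                        "e": 2 * len(coord_names) + len(mus_names),
                        "r": 2 * len(coord_names) + 2 * len(mus_names)}[block]
                for nm in names:
                    tw = twin(nm)
                    if tw not in index:
                        if exempt(f"{block}/{nm}"):
                            perm.append(base + index[nm])
                            continue
                        raise ValueError(
                            f"half-stride symmetry: {block}/{nm} has no contralateral "
                            f"twin and is not exempt"
                        )
                    perm.append(base + index[tw])
            perm = np.array(perm, dtype=int)

        keep = np.array([i for i, lb in enumerate(labels) if not exempt(lb)], dtype=int)
        self.sym_keep = keep
        self.sym_perm = perm
        self.sym_labels = [labels[i] for i in keep]
        self.sym_scale = self.scale[:self.npp][keep]  # kind scale per kept label

    def point_vector(self, z, s):
        return z[s * self.npp:(s + 1) * self.npp]

    def constraint_fun_multi(self, Z):
        """All nonlinear constraint rows for a stack of decision vectors:
        (K, n_vars) -> (K, n_rows).  Every collocation point of every stacked
        vector goes through the dynamics in one batched call."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        K = Z.shape[0]
        P, N, nx, nq, nm = self.P, self.N, self.nx, self.nq, self.nm
        tf = Z[:, -1]
        pts = Z[:, :-1].reshape(K * P, self.npp)
        Q = pts[:, :nq]
        U = pts[:, nq:2 * nq]
        Aact = pts[:, 2 * nq:2 * nq + nm]
        Eact = pts[:, 2 * nq + nm:2 * nq + 2 * nm]
        Ract = pts[:, 2 * nq + 2 * nm:]
        F = self.state_derivatives(Q, U, Aact, Eact, Ract).reshape(K, P, nx)
        X = self.states(Q, U, Aact).reshape(K, P, nx)
        h = (tf / N)[:, None, None]
        n_idx = np.arange(0, P - 1, 2)
        Xk, Xm, Xk1 = X[:, n_idx], X[:, n_idx + 1], X[:, n_idx + 2]
        Fk, Fm, Fk1 = F[:, n_idx], F[:, n_idx + 1], F[:, n_idx + 2]
        H = Xm - 0.5 * (Xk + Xk1) - (h / 8.0) * (Fk - Fk1)
        Sdef = Xk1 - Xk - (h / 6.0) * (Fk + 4.0 * Fm + Fk1)
        defects = (np.stack([H, Sdef], axis=2).reshape(K, 2 * N, nx)
                   / self.x_scale[None, None, :]).reshape(K, 2 * N * nx)

        out = [defects]
        for name, _ in self.row_layout[1:]:
            if name in ("sym_half", "sym_full"):
                start = Z[:, :self.npp]
                end = Z[:, (P - 1) * self.npp:P * self.npp]
                res = end[:, self.sym_keep] - start[:, self.sym_perm][:, self.sym_keep]
                out.append(res / self.sym_scale[None, :])
            elif name == "avg_speed":
                Qr = Q.reshape(K, P, nq)
                com = self.model.com_position(
                    np.concatenate([Qr[:, 0], Qr[:, -1]], axis=0))
                travel = com[K:, 0] - com[:K, 0]
                out.append((travel / tf - self.avg_speed_target)[:, None])
            elif name == "intersect":
                pl, pr, ll, lr = self.model.leg_landmark_points(Q)
                gap = np.sqrt((pl[:, 0] - pr[:, 0]) ** 2 + (ll - lr) ** 2)
                out.append(gap.reshape(K, P) - self.min_gap)
        return np.concatenate(out, axis=1)

    def constraint_fun(self, z):
        """All nonlinear constraint rows (scaled residual units)."""
        return self.constraint_fun_multi(z[None, :])[0]

    def raw_violation(self, z):
        """Max absolute violation in constraint (scaled-row) units, plus the
        per-family breakdown."""
        c = self.constraint_fun(z)
        viol = np.maximum(self.clb - c, 0) + np.maximum(c - self.cub, 0)
        report, row = {}, 0
        for name, n in self.row_layout:
            report[name] = float(np.max(viol[row:row + n])) if n else 0.0
            row += n
        # Bound violations are zero by construction with trust-constr.
        return float(viol.max()) if viol.size else 0.0, report

    # ------------------------------------------------------------ objective
    def _build_objective_terms(self):
        p, model = self.problem, self.model
        self.wm, self.wa = p.weights.control_weights(model, p.active_actuators)
        self.wm_active = self.wm[self.mus_active_idx]
        # Synergy groups restricted to active muscles, as column indices.
        mus_names = [model.muscle_names[i] for i in self.mus_active_idx]
        idx = {n: j for j, n in enumerate(mus_names)}
        self.syn_groups = []
        for g in model.muscle_groups.values():
            cols = [idx[m] for m in g.members if m in idx]
            if len(cols) >= 2:
                self.syn_groups.append(cols)
        self.energy_cols = [j for j, n in enumerate(mus_names)
                            if "rect_abd" in n.lower() or "ext_obl" in n.lower()]
        if p.mode == "tracking":
            ms = p.marker_set
            self.track_markers = ms.markers
            self.track_weights = ms.weights
            t_grid = self.tau * p.t_final
            self.ref_markers = p.reference.markers_at(t_grid, ms.names)
            self.ref_forces = p.reference.forces_at(t_grid, model.foot_sides)

    def per_point_costs_multi(self, Z):
        """Stacked per-point cost densities: (K, n_vars) -> (K, 2P) laid out
        as [main densities | effort densities]."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        K = Z.shape[0]
        p, w = self.problem, self.problem.weights
        P, nq, nm = self.P, self.nq, self.nm
        pts = Z[:, :-1].reshape(K * P, self.npp)
        Q = pts[:, :nq]
        U = pts[:, nq:2 * nq]
        Eact = pts[:, 2 * nq + nm:2 * nq + 2 * nm]
        Ract = pts[:, 2 * nq + 2 * nm:]
        main = np.zeros(K * P)
        for cols in self.syn_groups:
            e1 = Eact[:, cols[0]]
            main += w.w_s * (e1 - Eact[:, cols[1]]) ** 2
            if len(cols) == 3:
                main += w.w_s * (e1 - Eact[:, cols[2]]) ** 2
        for j in self.energy_cols:
            main += w.w_p * 10.0 * Eact[:, j] ** 2
        if p.mode == "tracking":
            pos = self.model.marker_positions(Q, self.track_markers)
            ref = np.tile(self.ref_markers, (K, 1, 1))
            err2 = ((pos - ref) ** 2).sum(axis=2)
            main += w.w_mt * (err2 @ self.track_weights)
            totals = self.model.foot_contact_totals(Q, U)
            ferr = np.zeros(K * P)
            for j, side in enumerate(self.model.foot_sides):
                ref_f = np.tile(self.ref_forces[:, j], (K, 1))
                ferr += ((totals[side] - ref_f) ** 2).sum(axis=1)
            main += w.w_ct * ferr / (self.model.total_mass * self.model.gravity)
        eff = (Eact**2) @ self.wm_active
        if self.na:
            eff = eff + (Ract**2) @ self.wa
        eff = w.w_e * eff
        return np.concatenate([main.reshape(K, P), eff.reshape(K, P)], axis=1)

    def per_point_costs(self, z):
        """(P,) main cost density and (P,) effort density (both unweighted by
        the distance factor), evaluated at every collocation point."""
        both = self.per_point_costs_multi(z[None, :])[0]
        return both[:self.P], both[self.P:]

    def com_travel(self, z):
        Q, _, _, _, _, _ = self.unpack(z)
        com = self.model.com_position(np.vstack([Q[0], Q[-1]]))
        return float(com[1, 0] - com[0, 0])

    def objective(self, z):
        main, eff = self.per_point_costs(z)
        tf = z[-1]
        J_main = tf * float(self.wq_tau @ main)
        J_eff = tf * float(self.wq_tau @ eff)
        if self.problem.mode == "tracking":
            d = self.com_travel(z)
            return J_main + d * J_eff
        if not self.problem.divide_effort_by_distance:
            return J_main + J_eff
        d_eff, _ = self.smooth_travel(self.com_travel(z))
        return J_main + J_eff / d_eff

    # Smooth floor (5 cm) on the CoM travel normalizing the effort term:
    # keeps 1/d and its gradient bounded while the iterate still crawls,
    # while leaving walking-scale distances essentially untouched.
    _D_FLOOR = 0.05
    _D_EPS = 0.005

    def smooth_travel(self, d):
        """(floored travel, derivative wrt raw travel)."""
        f, eps = self._D_FLOOR, self._D_EPS
        s = d - f
        r = np.sqrt(s * s + eps * eps)
        return f + 0.5 * (s + r), 0.5 * (1.0 + s / r)

    def objective_parts(self, z):
        main, eff = self.per_point_costs(z)
        tf = z[-1]
        return tf * float(self.wq_tau @ main), tf * float(self.wq_tau @ eff)


def transcribe(problem: OCProblem) -> Transcription:
    """Build the NLP realization of the problem (validates bounds/layout)."""
    return Transcription(problem)
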