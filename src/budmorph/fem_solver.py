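"""P1 finite-element steady-state solver for the ligand-receptor models
on subdomain-labelled triangulations.

Discretisation: linear triangles, mass lumping, zero-flux (natural)
boundary conditions everywhere. The receptor is assembled on epithelial
elements only (so the interface is naturally no-flux for R), while the
ligand(s) share nodes across the interface (continuity). Steady states
are reached by pseudo-transient continuation: linearised implicit Euler
steps with an adaptively growing time step and a lazily refactorised
Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import ConvergenceError, InputError
from .geometry import EPITHELIUM, Mesh, TwoLayerDomain, build_mesh
from .model_selection import deviation, normalize_growth, normalize_signal
from .rd_models import ModelSpec, effective_ligand_production, steady_state_wellmixed

__all__ = [
    "SteadyState",
    "SignalProfile",
    "Operators",
    "assemble_operators",
    "solve_steady",
    "signal_on_interface",
    "check_convergence",
    "integrate_diffusion",
]


@dataclass
class SteadyState:
    """Nodal steady-state values: R on epithelial nodes (``epi_nodes``
    gives their global indices), L (and L1 for T5) on all nodes."""

    R: np.ndarray
    L: np.ndarray
    L1: np.ndarray | None
    epi_nodes: np.ndarray
    residual_norm: float
    converged: bool
    n_steps: int = 0

    def R_global(self, n_nodes: int) -> np.ndarray:
        out = np.zeros(n_nodes)
        out[self.epi_nodes] = self.R
        return out

    def save_npz(self, path, mesh: Mesh | None = None):
        payload = {"R": self.R, "L": self.L, "epi_nodes": self.epi_nodes,
                   "converged": np.array([self.converged])}
        if self.L1 is not None:
            payload["L1"] = self.L1
        if mesh is not None:
            payload["nodes"] = mesh.nodes
        np.savez(path, **payload)


@dataclass
class SignalProfile:
    """Signalling readout R^m L^n sampled along the interface arc."""

    arc_positions: np.ndarray
    values: np.ndarray
    total_length: float
    closed: bool = True

    def __post_init__(self):
        if np.any(np.diff(self.arc_positions) <= 0):
            raise InputError("arc positions must be strictly increasing")
        if np.any(self.values < 0):
            raise InputError("signal values must be non-negative")

    def interp(self, s: np.ndarray) -> np.ndarray:
        if self.closed:
            s = np.mod(s, self.total_length)
            xp = np.concatenate([self.arc_positions, [self.total_length]])
            fp = np.concatenate([self.values, [self.values[0]]])
            return np.interp(s, xp, fp)
        return np.interp(s, self.arc_positions, self.values)


# ---------------------------------------------------------------------------
# assembly


def _p1_stiffness(nodes: np.ndarray, triangles: np.ndarray, n_nodes: int):
    """Stiffness matrix (grad phi_i . grad phi_j) over the given elements."""
    p = nodes[triangles]
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
    area = 0.5 * np.abs(area2)
    coef = 1.0 / (4.0 * area)
    ke = coef[:, None, None] * (b[:, :, None] * b[:, None, :]
                                + c[:, :, None] * c[:, None, :])
    rows = np.repeat(triangles, 3, axis=1).ravel()
    cols = np.tile(triangles, (1, 3)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_nodes, n_nodes))
    return K.tocsr(), area


def _lumped_mass(triangles: np.ndarray, areas: np.ndarray, n_nodes: int):
    m = np.zeros(n_nodes)
    np.add.at(m, triangles.ravel(), np.repeat(areas / 3.0, 3))
    return m


class Operators:
    """Pre-assembled spatial operators for one mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        n = mesh.n_nodes
        tri_e = mesh.triangles[mesh.subdomain_labels == EPITHELIUM]
        if len(tri_e) == 0:
            raise InputError("mesh has no epithelial elements")
        self.K_all, areas_all = _p1_stiffness(mesh.nodes, mesh.triangles, n)
        self.M_all = _lumped_mass(mesh.triangles, areas_all, n)

        self.epi_nodes = np.unique(tri_e)
        self.r_of_global = -np.ones(n, dtype=int)
        self.r_of_global[self.epi_nodes] = np.arange(len(self.epi_nodes))
        tri_e_local = self.r_of_global[tri_e]
        ne = len(self.epi_nodes)
        self.K_epi, areas_e = _p1_stiffness(mesh.nodes[self.epi_nodes],
                                            tri_e_local, ne)
        self.M_epi_local = _lumped_mass(tri_e_local, areas_e, ne)
        self.M_epi = np.zeros(n)
        self.M_epi[self.epi_nodes] = self.M_epi_local
        self.M_mes = self.M_all - self.M_epi
        self.n_nodes = n
        self.n_epi = ne


def assemble_operators(mesh: Mesh) -> Operators:
    return Operators(mesh)


# ---------------------------------------------------------------------------
# steady-state solve


def _source_field(model: ModelSpec, ops: Operators, L1) -> np.ndarray:
    """Per-node mesenchymal ligand production rate, including any extra
    sources attached by ``branching_sim.add_ligand_source``."""
    rho = effective_ligand_production(model, L1)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), (ops.n_nodes,)).copy()
    for src in getattr(model, "extra_sources", ()):
        if src["kind"] == "uniform":
            rho += src["rate"]
        else:  # bead
            d = np.linalg.norm(ops.mesh.nodes - np.asarray(src["location"]), axis=1)
            rho[d < src["radius"]] += src["rate"]
    return rho


def _residual(model: ModelSpec, ops: Operators, u, collapsed: bool):
    p = model.params
    ne, n = ops.n_epi, ops.n_nodes
    R = u[:ne]
    L = u[ne:ne + n]
    L1 = u[ne + n:] if model.has_second_ligand else None
    L_epi = L[ops.epi_nodes]
    q = R ** p.m * L_epi ** p.n

    F_R = (-p.D_R * (ops.K_epi @ R)
           + ops.M_epi_local * (p.rho_R - p.delta_R * R + p.w * q))

    rho_field = _source_field(model, ops, L1 if L1 is not None else 0.0)
    F_L = (-p.D_L * (ops.K_all @ L) + ops.M_mes * rho_field
           - ops.M_all * p.delta_L * L)
    np.add.at(F_L, ops.epi_nodes, ops.M_epi_local * (-p.n * p.mu * q))
    if collapsed:
        np.add.at(F_L, ops.epi_nodes, ops.M_epi_local * p.rho_L)

    if model.has_second_ligand:
        F_L1 = -p.D_L1 * (ops.K_all @ L1) - ops.M_all * p.delta_L1 * L1
        np.add.at(F_L1, ops.epi_nodes, ops.M_epi_local * p.b_1 * q)
        return np.concatenate([F_R, F_L, F_L1])
    return np.concatenate([F_R, F_L])


def _jacobian(model: ModelSpec, ops: Operators, u, collapsed: bool):
    p = model.params
    ne, n = ops.n_epi, ops.n_nodes
    R = u[:ne]
    L = u[ne:ne + n]
    L1 = u[ne + n:] if model.has_second_ligand else None
    L_epi = L[ops.epi_nodes]
    qR = p.m * R ** (p.m - 1) * L_epi ** p.n
    qL = p.n * R ** p.m * (L_epi ** (p.n - 1) if p.n > 1 else 1.0)

    Me = ops.M_epi_local
    J_RR = -p.D_R * ops.K_epi + sp.diags(Me * (-p.delta_R + p.w * qR))
    # R-L coupling: diagonal over shared epithelial nodes
    J_RL = sp.coo_matrix((Me * p.w * qL,
                          (np.arange(ne), ops.epi_nodes)), shape=(ne, n))
    J_LR = sp.coo_matrix((Me * (-p.n * p.mu * qR),
                          (ops.epi_nodes, np.arange(ne))), shape=(n, ne))
    add_LL = np.zeros(n)
    add_LL[ops.epi_nodes] = Me * (-p.n * p.mu * qL)
    J_LL = -p.D_L * ops.K_all + sp.diags(-ops.M_all * p.delta_L + add_LL)

    if not model.has_second_ligand:
        return sp.bmat([[J_RR, J_RL], [J_LR, J_LL]], format="csc")

    drho = ((p.gamma * p.K_fb / (p.K_fb + L1) ** 2) if p.gamma > 0
            else np.zeros(n))
    J_LL1 = sp.diags(ops.M_mes * drho)
    J_L1R = sp.coo_matrix((Me * p.b_1 * qR,
                           (ops.epi_nodes, np.arange(ne))), shape=(n, ne))
    d_L1L = np.zeros(n)
    d_L1L[ops.epi_nodes] = Me * p.b_1 * qL
    J_L1L = sp.diags(d_L1L)
    J_L1L1 = -p.D_L1 * ops.K_all - sp.diags(ops.M_all * p.delta_L1)
    Z = sp.coo_matrix((ne, n))
    return sp.bmat([[J_RR, J_RL, Z],
                    [J_LR, J_LL, J_LL1],
                    [J_L1R, J_L1L, J_L1L1]], format="csc")


def solve_steady(model: ModelSpec, mesh_or_ops, init=None, seed: int = 0,
                 tol: float = 1e-6, max_steps: int = 100_000,
                 collapsed: bool = False, perturbation: float = 1e-3,
                 dt0: float = 0.1, dt_max: float = 1e5,
                 refactor_every: int = 25,
                 raise_on_failure: bool = False) -> SteadyState:
    """March the RD system to steady state on a static mesh.

    The initial condition is the homogeneous collapsed steady state plus
    a seeded uniform perturbation of relative amplitude ``perturbation``
    (or ``init``: a full dof vector, or a callable
    ``init(points, species)`` evaluated on node coordinates).
    Convergence: maximum relative change per unit time below ``tol``.

    ``collapsed=True`` adds the mesenchymal ligand source to epithelial
    elements too (single-layer convention used for stability-analysis
    concordance checks on simple domains).
    """
    ops = (mesh_or_ops if isinstance(mesh_or_ops, Operators)
           else Operators(mesh_or_ops))
    if tol <= 0:
        raise InputError("tol must be positive")
    p = model.params
    ne, n = ops.n_epi, ops.n_nodes
    ndof = ne + n * (2 if model.has_second_ligand else 1)

    if init is None:
        try:
            ss = steady_state_wellmixed(model)
        except Exception:
            ss = (p.rho_R / max(p.delta_R, 1e-12), p.rho_L / max(p.delta_L, 1e-12))
            if model.has_second_ligand:
                ss = (*ss, 0.0)
        rng = np.random.default_rng(seed)
        u = np.concatenate(
            [np.full(ne, ss[0]), np.full(n, ss[1])]
            + ([np.full(n, ss[2])] if model.has_second_ligand else []))
        u *= 1.0 + perturbation * rng.uniform(-1, 1, size=ndof)
        u = np.maximum(u, 0.0)
    elif callable(init):
        vals = [np.asarray(init(ops.mesh.nodes[ops.epi_nodes], "R"), dtype=float),
                np.asarray(init(ops.mesh.nodes, "L"), dtype=float)]
        if model.has_second_ligand:
            vals.append(np.asarray(init(ops.mesh.nodes, "L1"), dtype=float))
        u = np.concatenate(vals)
    else:
        u = np.asarray(init, dtype=float).copy()
        if len(u) != ndof:
            raise InputError(f"init has {len(u)} dofs, expected {ndof}")

    Mdiag = np.concatenate(
        [ops.M_epi_local, ops.M_all]
        + ([ops.M_all] if model.has_second_ligand else []))
    scale = max(float(np.max(u)), p.rho_R / max(p.delta_R, 1e-12), 1e-12)
    cap = 1e9 * scale

    dt = dt0
    lu = None
    lu_dt = None
    since_refactor = 0
    F = _residual(model, ops, u, collapsed)
    bad_streak = 0
    for step in range(1, max_steps + 1):
        if lu is None or lu_dt != dt:
            A = sp.diags(Mdiag / dt) - _jacobian(model, ops, u, collapsed)
            lu = splu(A.tocsc())
            lu_dt = dt
            since_refactor = 0
        delta = lu.solve(F)
        u_new = u + delta
        if not np.all(np.isfinite(u_new)) or np.max(np.abs(u_new)) > cap:
            if dt <= 1e-12:
                raise ConvergenceError(
                    f"blow-up while solving {model.variant} with {p}")
            dt *= 0.25
            lu = None
            continue
        if np.min(u_new) < -1e-6 * scale:
            dt *= 0.5
            lu = None
            if dt < 1e-12:
                raise ConvergenceError(
                    f"persistent negativity for {model.variant} with {p}")
            continue
        np.clip(u_new, 0.0, None, out=u_new)
        F_new = _residual(model, ops, u_new, collapsed)
        if np.linalg.norm(F_new) > 2.0 * np.linalg.norm(F) + 1e-300:
            bad_streak += 1
            if bad_streak >= 3:
                dt = max(dt * 0.25, 1e-10)
                lu = None
                bad_streak = 0
        else:
            bad_streak = 0
        u, F = u_new, F_new
        unorm = float(np.max(np.abs(u)))
        change_rate = float(np.max(np.abs(delta))) / (dt * max(unorm, 1e-30))
        if change_rate < tol and step > 3:
            return SteadyState(R=u[:ne], L=u[ne:ne + n],
                               L1=u[ne + n:] if model.has_second_ligand else None,
                               epi_nodes=ops.epi_nodes,
                               residual_norm=float(np.linalg.norm(F)),
                               converged=True, n_steps=step)
        since_refactor += 1
        if since_refactor >= refactor_every:
            lu = None
        if step % 3 == 0 and dt < dt_max:
            dt = min(dt * 4.0, dt_max)
            lu = None
    if raise_on_failure:
        raise ConvergenceError(
            f"no steady state within {max_steps} steps for {model.variant}")
    return SteadyState(R=u[:ne], L=u[ne:ne + n],
                       L1=u[ne + n:] if model.has_second_ligand else None,
                       epi_nodes=ops.epi_nodes,
                       residual_norm=float(np.linalg.norm(F)),
                       converged=False, n_steps=max_steps)


# ---------------------------------------------------------------------------
# interface profile extraction


def signal_on_interface(state: SteadyState, mesh: Mesh, n_samples: int = 400,
                        model: ModelSpec | None = None,
                        readout_exponents: tuple[int, int] = (2, 1),
                        loop_index: int = 0,
                        require_converged: bool = True) -> SignalProfile:
    """Interpolate R^m L^n at ``n_samples`` uniformly arc-spaced points of
    the interface (the epithelial boundary minus any stalk interval)."""
    if require_converged and not state.converged:
        raise ConvergenceError("refusing to sample an unconverged state")
    if model is not None:
        readout_exponents = model.readout_exponents
    m, n_exp = readout_exponents

    loop = mesh.interface_loops[loop_index]
    R_glob = state.R_global(mesh.n_nodes)
    vals = R_glob[loop] ** m * state.L[loop] ** n_exp

    stalk = (mesh.stalk_node_mask[loop]
             if mesh.stalk_node_mask is not None else np.zeros(len(loop), bool))
    pts = mesh.nodes[loop]
    if (not stalk.any() and mesh.interface_arcs is not None
            and mesh.curve_lengths is not None):
        # exact arc parametrisation of the source curve: identical across
        # mesh resolutions, so profiles from different h align exactly
        arc = np.asarray(mesh.interface_arcs[loop_index], dtype=float)
        total = float(mesh.curve_lengths[loop_index])
        s = np.linspace(0.0, total, n_samples, endpoint=False)
        out = np.interp(s, np.concatenate([arc, [total]]),
                        np.concatenate([vals, [vals[0]]]))
        return SignalProfile(arc_positions=s, values=np.maximum(out, 0.0),
                             total_length=total, closed=True)
    if stalk.any():
        # rotate so the non-stalk (interface) stretch is contiguous
        idx = np.where(~stalk)[0]
        breaks = np.where(np.diff(idx) > 1)[0]
        if len(breaks):
            idx = np.roll(idx, -(breaks[0] + 1))
        pts_i, vals_i = pts[idx], vals[idx]
        seg = np.linalg.norm(np.diff(pts_i, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        s = np.linspace(0.0, total, n_samples)
        out = np.interp(s, arc, vals_i)
        return SignalProfile(arc_positions=s, values=np.maximum(out, 0.0),
                             total_length=total, closed=False)
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    s = np.linspace(0.0, total, n_samples, endpoint=False)
    out = np.interp(s, arc, np.concatenate([vals, [vals[0]]]))
    return SignalProfile(arc_positions=s, values=np.maximum(out, 0.0),
                         total_length=total, closed=True)


# ---------------------------------------------------------------------------
# convergence study


def check_convergence(model: ModelSpec, domain: TwoLayerDomain,
                      h_values, reference_h: float, profile_E,
                      n_samples: int = 400, seed: int = 0,
                      tol: float = 1e-8, h_far: float | None = None,
                      init=None):
    """Deviation Delta at each mesh size versus a refined reference.

    ``profile_E`` holds the measured growth magnitudes: a callable of
    arc position or an array matching ``n_samples``. Returns a dict with
    per-h Delta and relative errors |Delta_h - Delta_ref| / Delta_ref.
    """
    h_values = list(h_values)
    if any(h <= reference_h for h in h_values):
        raise InputError("all h_values must exceed reference_h")

    def delta_at(h, far):
        mesh = build_mesh(domain, target_h=h, h_far=far)
        state = solve_steady(model, mesh, seed=seed, tol=tol, init=init)
        prof = signal_on_interface(state, mesh, n_samples=n_samples, model=model)
        C = normalize_signal(prof.values)
        E_vals = (profile_E(prof.arc_positions) if callable(profile_E)
                  else np.asarray(profile_E, dtype=float))
        E = normalize_growth(E_vals)
        return deviation(C, E, prof.arc_positions), mesh.n_nodes

    results = {}
    d_ref, n_ref = delta_at(reference_h, h_far)
    for h in h_values:
        d_h, n_h = delta_at(h, None)
        results[h] = {"delta": d_h, "n_nodes": n_h,
                      "rel_error": abs(d_h - d_ref) / d_ref}
    results["reference"] = {"h": reference_h, "delta": d_ref, "n_nodes": n_ref}
    return results


# ---------------------------------------------------------------------------
# utilities


def integrate_diffusion(mesh: Mesh, D: float, u0: np.ndarray, dt: float,
                        n_steps: int) -> np.ndarray:
    """Implicit-Euler pure diffusion with zero-flux boundaries (used for
    discrete mass-conservation checks: sum(M u) is invariant)."""
    ops = Operators(mesh)
    A = sp.diags(ops.M_all / dt) + D * ops.K_all
    lu = splu(A.tocsc())
    u = np.asarray(u0, dtype=float).copy()
    for _ in range(n_steps):
        u = lu.solve(ops.M_all * u / dt)
    return u
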