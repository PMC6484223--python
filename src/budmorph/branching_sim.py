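"""Free-boundary branching morphogenesis: the epithelial interface
advances along its outward normal at a speed proportional to a
saturating function of the local signalling readout, the outer
mesenchyme expands at constant speed, and the domain is re-meshed at
regular intervals with the solution mapped forward (quasi-steady-state
growth)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .errors import GeometryError, InputError
from .fem_solver import Operators, SignalProfile, signal_on_interface, solve_steady
from .geometry import (BoundaryCurve, Ellipse2D, TwoLayerDomain, build_mesh)
from .rd_models import ModelSpec

__all__ = [
    "GrowthLaw",
    "BranchEventLog",
    "ClassificationResult",
    "grow_step",
    "simulate_branching",
    "detect_tips",
    "classify_elongation",
    "lambda_fraction",
    "two_bud_experiment",
    "add_ligand_source",
]


@dataclass(frozen=True)
class GrowthLaw:
    """Boundary kinematics: interface speed v_g * f(signal) along the
    outward normal with a saturating (Hill) response f, and constant
    outward expansion of the outer mesenchyme boundary."""

    v_g: float = 0.04
    K_g: float = 1.0
    h_g: float = 2.0
    outer_speed: float | None = None

    def __post_init__(self):
        if self.v_g < 0 or self.K_g <= 0 or self.h_g <= 0:
            raise InputError("growth law needs v_g >= 0, K_g > 0, h_g > 0")
        if self.outer_speed is None:
            object.__setattr__(self, "outer_speed", self.v_g)

    def f(self, signal):
        s = np.asarray(signal, dtype=float)
        sh = s ** self.h_g
        return sh / (self.K_g ** self.h_g + sh)


@dataclass
class BranchEventLog:
    times: list = field(default_factory=list)
    tip_counts: list = field(default_factory=list)  # (before, after)
    labels: list = field(default_factory=list)

    def record(self, time: float, before: int, after: int):
        if after <= before:
            return
        delta = after - before
        label = {1: "bifurcation", 2: "trifurcation"}.get(delta, "multifurcation")
        self.times.append(time)
        self.tip_counts.append((before, after))
        self.labels.append(label)

    @property
    def n_events(self) -> int:
        return len(self.times)

    def to_rows(self):
        return [{"time": t, "tips_before": b, "tips_after": a, "label": lab}
                for t, (b, a), lab in zip(self.times, self.tip_counts, self.labels)]

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame(self.to_rows()).to_csv(path, index=False)


@dataclass
class ClassificationResult:
    """Elongation-mode classification of a signalling pattern on (a pair
    of) bud interfaces: requires high amplitude, a single peak, and a
    centred peak on every tip."""

    elongation: bool
    criterion_flags: dict
    per_tip: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# tip detection


def _closed_curvature(points: np.ndarray) -> np.ndarray:
    """Signed curvature at the vertices of a closed polyline (positive on
    convex stretches of a CCW curve), by periodic central differences."""
    d1 = (np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)) / 2.0
    d2 = np.roll(points, -1, axis=0) - 2 * points + np.roll(points, 1, axis=0)
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    den[den < 1e-30] = 1e-30
    return num / den


def detect_tips(curve: BoundaryCurve, curvature_threshold: float = 0.05,
                min_separation: float | None = None, n_samples: int = 400,
                smooth_frac: float = 0.02):
    """Tips = local maxima of outward curvature above the threshold,
    non-maximum-suppressed within ``min_separation`` arc length.

    Coordinates and the curvature signal are smoothed periodically over
    ``smooth_frac`` of the curve before peak finding (polygon sampling
    makes raw central-difference curvature extremely noisy).

    Returns (positions (k, 2), arc_positions (k,))."""
    from scipy.ndimage import uniform_filter1d

    if min_separation is None:
        min_separation = 0.05 * curve.total_length
    res = curve.resample(n_samples)
    win = max(3, int(smooth_frac * n_samples))
    pts = np.column_stack([
        uniform_filter1d(res.points[:, 0], win, mode="wrap"),
        uniform_filter1d(res.points[:, 1], win, mode="wrap")])
    kappa = _closed_curvature(pts)
    kappa = uniform_filter1d(kappa, win, mode="wrap")
    # periodic peak finding: tile and keep the central copy
    tiled = np.concatenate([kappa, kappa, kappa])
    ds = curve.total_length / n_samples
    dist = max(1, int(np.ceil(min_separation / ds)))
    peaks, props = find_peaks(tiled, height=curvature_threshold,
                              distance=dist,
                              prominence=0.25 * curvature_threshold)
    central = peaks[(peaks >= n_samples) & (peaks < 2 * n_samples)] - n_samples
    arc = res.arc_positions[central]
    return res.points[central], arc


# ---------------------------------------------------------------------------
# boundary evolution


def _advance_curve(curve: BoundaryCurve, speed_of_arc, dt: float,
                   resample_ds: float | None = None) -> BoundaryCurve:
    from scipy.ndimage import uniform_filter1d

    s = curve.arc_positions
    speeds = np.asarray(speed_of_arc(s), dtype=float)
    # smooth the normal directions over a few vertices: raw polygon
    # normals are noisy and make adjacent advanced points cross
    normals = curve.outward_normals()
    if curve.stalk_interval is None and len(normals) > 8:
        normals = np.column_stack([
            uniform_filter1d(normals[:, 0], 3, mode="wrap"),
            uniform_filter1d(normals[:, 1], 3, mode="wrap")])
        nn = np.linalg.norm(normals, axis=1, keepdims=True)
        nn[nn == 0] = 1.0
        normals = normals / nn
    frozen = np.zeros(len(s), dtype=bool)
    if curve.stalk_interval is not None:
        s0, s1 = curve.stalk_interval
        span = (s1 - s0) % curve.total_length
        frozen = ((s - s0) % curve.total_length) < span
    disp = np.where(frozen[:, None], 0.0, speeds[:, None] * normals * dt)
    new_pts = curve.points + disp
    new = BoundaryCurve(new_pts, stalk_interval=curve.stalk_interval,
                        spline_degree=curve.spline_degree)
    if resample_ds is not None and curve.stalk_interval is None:
        n = max(64, int(np.ceil(new.total_length / resample_ds)))
        # offset so no vertex is pinned across repeated resampling (a
        # pinned vertex accumulates a spurious curvature kink)
        new = new.resample(n, offset=0.37 * new.total_length / n)
    return new


def grow_step(state, domain: TwoLayerDomain, law: GrowthLaw, dt: float,
              mesh=None, model: ModelSpec | None = None,
              profiles=None, signal_lookups=None, max_halvings: int = 5,
              resample_ds: float | None = None) -> TwoLayerDomain:
    """One explicit front-tracking step: each interface point advances by
    n * v_g * f(signal) * dt, the outer boundary expands at constant
    speed, stalk points stay fixed. On self-intersection the step is
    retried with dt halved (up to ``max_halvings``).

    The signal driving the interface comes either from arc-parameterised
    ``profiles`` (one SignalProfile per epithelial curve) or from
    spatially anchored ``signal_lookups`` (callables mapping point
    coordinates to signal values; robust to re-parameterisation)."""
    if profiles is None and signal_lookups is None:
        if mesh is None or model is None:
            raise InputError("grow_step needs profiles, signal_lookups, "
                             "or (mesh, model)")
        profiles = [signal_on_interface(state, mesh, model=model, loop_index=i)
                    for i in range(len(domain.epithelia))]

    for attempt in range(max_halvings + 1):
        step_dt = dt / (2 ** attempt)
        try:
            new_curves = []
            for k, curve in enumerate(domain.epithelia):
                if signal_lookups is not None:
                    lookup = signal_lookups[k]

                    def speed(s, curve=curve, lookup=lookup):
                        pts = curve.points_at(np.asarray(s, dtype=float))
                        return law.v_g * law.f(lookup(pts))
                else:
                    prof = profiles[k]
                    scale = curve.total_length / prof.total_length \
                        if prof.total_length > 0 else 1.0

                    def speed(s, prof=prof, scale=scale):
                        return law.v_g * law.f(prof.interp(np.asarray(s) / scale))

                new_curves.append(_advance_curve(curve, speed, step_dt,
                                                 resample_ds=resample_ds))
            ell = domain.mesenchyme
            d_out = law.outer_speed * step_dt
            new_ell = Ellipse2D(ell.center,
                                (ell.semi_axes[0] + d_out,
                                 ell.semi_axes[1] + d_out),
                                ell.orientation)
            return TwoLayerDomain(tuple(new_curves), new_ell)
        except GeometryError:
            if attempt == max_halvings:
                raise GeometryError(
                    "growth step kept self-intersecting after "
                    f"{max_halvings} dt halvings")
    raise AssertionError("unreachable")


def _confirm(log: BranchEventLog, confirmed: int, n_now: int, t: float,
             pending, streak: int, t_pending: float, confirm_steps: int):
    """Debounced tip-count tracking: a changed count must persist for
    ``confirm_steps`` consecutive detections before an event is logged
    (transient curvature flickers otherwise masquerade as events)."""
    if n_now == confirmed:
        return None, 0, t_pending
    if pending is not None and n_now == pending:
        streak += 1
    else:
        pending, streak, t_pending = n_now, 1, t
    if streak >= confirm_steps:
        log.record(t_pending, confirmed, pending)
    return pending, streak, t_pending


def _map_state(old_state, old_mesh, model, new_ops: Operators) -> np.ndarray:
    """Nearest-node transfer of nodal values onto a new mesh."""
    tree_all = cKDTree(old_mesh.nodes)
    _, j_all = tree_all.query(new_ops.mesh.nodes)
    L_new = old_state.L[j_all]
    old_epi = old_mesh.nodes[old_state.epi_nodes]
    tree_epi = cKDTree(old_epi)
    _, j_epi = tree_epi.query(new_ops.mesh.nodes[new_ops.epi_nodes])
    R_new = old_state.R[j_epi]
    parts = [R_new, L_new]
    if old_state.L1 is not None:
        parts.append(old_state.L1[j_all])
    return np.concatenate(parts)


def simulate_branching(model: ModelSpec, init: TwoLayerDomain, law: GrowthLaw,
                       t_end: float, remesh_every: int = 10, seed: int = 0,
                       target_h: float = 2.0, dt: float | None = None,
                       curvature_threshold: float = 0.05,
                       min_separation: float | None = None,
                       solver_tol: float = 1e-5, resample_ds: float | None = None,
                       profile_smooth_arc: float = 0.0,
                       confirm_steps: int = 3, solver_max_steps: int = 4000,
                       record_shapes: bool = True,
                       record_profiles: bool = False):
    """Quasi-steady free-boundary growth: alternate steady-state solves
    and ``remesh_every`` front-tracking steps per re-mesh cycle; tips are
    tracked per cycle and count increases logged as branch events.

    Returns (shapes, event_log, tip_history); with
    ``record_profiles=True`` a fourth list of per-cycle interface
    profiles (arc_positions, values, total_length) is appended, each
    matching the domain recorded at the same cycle index."""
    if dt is None:
        # CFL-like: max boundary displacement per step <= h/4
        dt = 0.25 * target_h / max(law.v_g, 1e-12)
    domain = init
    t = 0.0
    shapes = [(0.0, domain)] if record_shapes else []
    log = BranchEventLog()
    tip_history = []
    prev_state = None
    prev_mesh = None
    confirmed = None
    pending = None
    streak = 0
    t_pending = 0.0
    profiles_log = []
    if resample_ds is None:
        resample_ds = 0.75 * target_h

    while t < t_end - 1e-9:
        mesh = build_mesh(domain, target_h=target_h)
        ops = Operators(mesh)
        init_vec = (None if prev_state is None
                    else _map_state(prev_state, prev_mesh, model, ops))
        state = solve_steady(model, ops, init=init_vec, seed=seed,
                             tol=solver_tol, max_steps=solver_max_steps)
        if not state.converged:
            state = solve_steady(model, ops, seed=seed, tol=solver_tol,
                                 max_steps=solver_max_steps)
        prev_state, prev_mesh = state, mesh

        def count_tips(dom):
            tips = []
            for curve in dom.epithelia:
                pos, _arc = detect_tips(curve, curvature_threshold,
                                        min_separation)
                tips.extend(pos)
            return max(len(tips), 1), np.asarray(tips)

        n_tips, tips_now = count_tips(domain)
        tip_history.append((t, n_tips, tips_now))
        if confirmed is None:
            confirmed = n_tips
        pending, streak, t_pending = _confirm(log, confirmed, n_tips, t,
                                              pending, streak, t_pending,
                                              confirm_steps)
        if streak >= confirm_steps and pending is not None:
            confirmed, pending, streak = pending, None, 0

        # spatially anchored signal lookup: values at the interface nodes
        # (smoothed along the loop), interpolated by nearest nodes; this
        # is independent of curve re-parameterisation during growth
        from scipy.ndimage import uniform_filter1d

        signal_lookups = []
        m_exp, n_exp = model.readout_exponents
        R_glob = state.R_global(mesh.n_nodes)
        for i, loop in enumerate(mesh.interface_loops):
            vals = R_glob[loop] ** m_exp * state.L[loop] ** n_exp
            if profile_smooth_arc > 0:
                spacing = 0.8 * target_h
                win = max(1, int(profile_smooth_arc / spacing))
                vals = uniform_filter1d(vals, win, mode="wrap")
            tree = cKDTree(mesh.nodes[loop])

            def lookup(pts, tree=tree, vals=vals):
                d, j = tree.query(pts, k=3)
                w = 1.0 / np.maximum(d, 1e-9)
                return np.sum(w * vals[j], axis=1) / np.sum(w, axis=1)

            signal_lookups.append(lookup)

        if record_profiles:
            loop = mesh.interface_loops[0]
            arc = (np.asarray(mesh.interface_arcs[0])
                   if mesh.interface_arcs is not None else None)
            vals0 = R_glob[loop] ** m_exp * state.L[loop] ** n_exp
            profiles_log.append((arc, vals0,
                                 float(mesh.curve_lengths[0])
                                 if mesh.curve_lengths else None))

        for _ in range(remesh_every):
            if t >= t_end - 1e-9:
                break
            step_dt = min(dt, t_end - t)
            domain = grow_step(None, domain, law, step_dt,
                               signal_lookups=signal_lookups,
                               resample_ds=resample_ds)
            t += step_dt
            # tips tracked per growth step so the event log does not
            # depend on the remeshing cadence
            n_tips, tips_now = count_tips(domain)
            tip_history.append((t, n_tips, tips_now))
            pending, streak, t_pending = _confirm(log, confirmed, n_tips, t,
                                                  pending, streak, t_pending,
                                                  confirm_steps)
            if streak >= confirm_steps and pending is not None:
                confirmed, pending, streak = pending, None, 0
        # keep vertex spacing tied to the mesh size between remeshes
        new_curves = []
        for c in domain.epithelia:
            if c.stalk_interval is None:
                n = max(64, int(np.ceil(c.total_length / resample_ds)))
                new_curves.append(c.resample(n))
            else:
                new_curves.append(c)
        domain = TwoLayerDomain(tuple(new_curves), domain.mesenchyme)
        if record_shapes:
            shapes.append((t, domain))
    if record_profiles:
        return shapes, log, tip_history, profiles_log
    return shapes, log, tip_history


# ---------------------------------------------------------------------------
# pattern classification


def _single_bud_flags(profile: SignalProfile, centre_arc: float,
                      amplitude_ratio: float = 5.0,
                      centre_tolerance: float = 0.10,
                      prominence_frac: float = 0.05,
                      window_frac: float | None = None,
                      smooth_arc: float = 0.0) -> dict:
    """Criteria for one bud: amplitude ratio over the full interface;
    peak count and centring evaluated inside a window of ``window_frac``
    of the interface length around the bud centre (the tip region), or
    over the whole profile when ``window_frac`` is None."""
    vals = np.asarray(profile.values, dtype=float)
    if len(vals) == 0 or np.all(vals == 0):
        raise InputError("empty or all-zero profile")
    if smooth_arc > 0 and len(vals) > 4:
        from scipy.ndimage import uniform_filter1d
        ds = profile.total_length / len(vals)
        vals = uniform_filter1d(vals, max(1, int(smooth_arc / ds)),
                                mode="wrap" if profile.closed else "nearest")
    vmin = max(vals.min(), 1e-300)
    amp_ok = (vals.max() / vmin) > amplitude_ratio

    P = profile.total_length
    if window_frac is not None and profile.closed:
        rel = (profile.arc_positions - centre_arc + P / 2) % P - P / 2
        order = np.argsort(rel)
        sel = np.abs(rel[order]) <= 0.5 * window_frac * P
        w = vals[order][sel]
        x = rel[order][sel]
        rng = w.max() - w.min()
        peaks, _ = find_peaks(w, prominence=prominence_frac * max(rng, 1e-300))
        single = len(peaks) == 1
        centred = single and abs(x[peaks[0]]) <= centre_tolerance * P
    else:
        rng = vals.max() - vals.min()
        if profile.closed:
            tiled = np.concatenate([vals, vals, vals])
            peaks, _ = find_peaks(tiled,
                                  prominence=prominence_frac * max(rng, 1e-300))
            n = len(vals)
            peaks = peaks[(peaks >= n) & (peaks < 2 * n)] - n
        else:
            peaks, _ = find_peaks(vals,
                                  prominence=prominence_frac * max(rng, 1e-300))
        single = len(peaks) == 1
        centred = False
        if single:
            d = abs(profile.arc_positions[peaks[0]] - centre_arc)
            if profile.closed:
                d = min(d, P - d)
            centred = d <= centre_tolerance * P
    return {"amplitude": bool(amp_ok), "single_peak": bool(single),
            "centred": bool(centred),
            "n_peaks": int(len(peaks))}


def classify_elongation(profiles, centre_arcs, amplitude_ratio: float = 5.0,
                        centre_tolerance: float = 0.10,
                        prominence_frac: float = 0.05,
                        window_frac: float | None = None,
                        smooth_arc: float = 0.0) -> ClassificationResult:
    """Elongation mode: on BOTH tips the signalling pattern must have
    max/min above ``amplitude_ratio``, exactly one peak, and the peak
    within ``centre_tolerance`` (fraction of the bud's interface length)
    of the bud centre."""
    per_tip = [_single_bud_flags(p, c, amplitude_ratio, centre_tolerance,
                                 prominence_frac, window_frac, smooth_arc)
               for p, c in zip(profiles, centre_arcs)]
    flags = {
        "amplitude": all(t["amplitude"] for t in per_tip),
        "single_peak": all(t["single_peak"] for t in per_tip),
        "centred": all(t["centred"] for t in per_tip),
    }
    return ClassificationResult(elongation=all(flags.values()),
                                criterion_flags=flags, per_tip=per_tip)


def lambda_fraction(results) -> float:
    """Fraction of parameter sets supporting the elongation mode,
    Lambda = n_el / n_t in [0, 1]."""
    results = list(results)
    if not results:
        raise InputError("empty classification list")
    flags = [r.elongation if isinstance(r, ClassificationResult) else bool(r)
             for r in results]
    return sum(flags) / len(flags)


# ---------------------------------------------------------------------------
# two-bud feedback experiment


def two_bud_experiment(variants, l0_grid, param_sets, law: GrowthLaw | None = None,
                       seed: int = 0, bud_length: float = 25.0,
                       bud_width: float = 10.0, alpha: float = 3.0,
                       target_h: float = 2.5, solver_tol: float = 1e-5,
                       max_steps: int = 100_000,
                       amplitude_ratio: float = 5.0):
    """Static classification screen on two opposing buds at decreasing
    tip-to-tip distances l0.

    For each (variant, l0, parameter set) the steady state is solved and
    the elongation criteria evaluated on both bud interfaces. Returns a
    dict with, per variant: Lambda per l0, per-set elongation flags, the
    per-set minimal sustaining l0 (smallest grid l0 with elongation at it
    and at all larger grid values), and the variant's overall minimum.
    """
    from .geometry import Ellipse2D
    from .synthetic_data import two_bud_domain_curves

    l0_grid = list(l0_grid)
    if any(np.diff(l0_grid) >= 0):
        raise InputError("l0_grid must be strictly decreasing")

    domains = {}
    meshes = {}
    for l0 in l0_grid:
        left, right = two_bud_domain_curves(l0, bud_length, bud_width)
        # a moment-derived ellipse degenerates to a sliver for this
        # elongated arrangement; surround the buds explicitly instead
        semi_x = (l0 / 2 + 2 * bud_length) * 1.15 + 0.2 * alpha * bud_length
        semi_y = max(alpha * 1.5 * bud_width, 0.35 * semi_x)
        ell = Ellipse2D(np.array([0.0, 0.0]), (semi_x, semi_y),
                        np.array([1.0, 0.0]))
        dom = TwoLayerDomain((left, right), ell)
        domains[l0] = dom
        meshes[l0] = build_mesh(dom, target_h=target_h)

    out = {}
    for variant in variants:
        elong = np.zeros((len(param_sets), len(l0_grid)), dtype=bool)
        for j, params in enumerate(param_sets):
            for i, l0 in enumerate(l0_grid):
                model = ModelSpec(variant, params)
                mesh = meshes[l0]
                try:
                    state = solve_steady(model, mesh, seed=seed, tol=solver_tol,
                                         max_steps=max_steps)
                except Exception:
                    continue
                if not state.converged:
                    continue
                try:
                    profs, centres = [], []
                    for k, curve in enumerate(domains[l0].epithelia):
                        prof = signal_on_interface(state, mesh, model=model,
                                                   loop_index=k)
                        # facing tip apex: rightmost point of the left bud,
                        # leftmost point of the right bud
                        loop_pts = mesh.nodes[mesh.interface_loops[k]]
                        apex = (np.argmax(loop_pts[:, 0]) if k == 0
                                else np.argmin(loop_pts[:, 0]))
                        arc = np.asarray(mesh.interface_arcs[k])
                        profs.append(prof)
                        centres.append(float(arc[apex]))
                    res = classify_elongation(profs, centres,
                                              amplitude_ratio=amplitude_ratio,
                                              window_frac=0.5, smooth_arc=3.0)
                    elong[j, i] = res.elongation
                except InputError:
                    continue
        lam_per_l0 = elong.mean(axis=0)
        min_l0 = np.full(len(param_sets), np.nan)
        for j in range(len(param_sets)):
            run = None
            for i, l0 in enumerate(l0_grid):  # decreasing
                if elong[j, i]:
                    run = l0
                else:
                    break
            if run is not None:
                min_l0[j] = run
        finite = min_l0[~np.isnan(min_l0)]
        out[variant] = {
            "l0_grid": l0_grid,
            "lambda_per_l0": lam_per_l0,
            "lambda": float(elong.any(axis=1).mean()),
            "elongation": elong,
            "min_l0_per_set": min_l0,
            "min_l0": float(np.min(finite)) if len(finite) else np.inf,
        }
    return out


# ---------------------------------------------------------------------------
# perturbations


def add_ligand_source(model: ModelSpec, kind: str, location=None,
                      rate: float = 0.0, radius: float = 0.0,
                      domain: TwoLayerDomain | None = None) -> ModelSpec:
    """Attach an extra ligand source: 'uniform' raises mesenchymal
    production everywhere; 'bead' adds a localised disc source."""
    if rate < 0:
        raise InputError("rate must be >= 0")
    if kind not in ("uniform", "bead"):
        raise InputError("kind must be 'uniform' or 'bead'")
    if rate == 0:
        return model
    if kind == "bead":
        if location is None or radius <= 0:
            raise InputError("bead source needs a location and radius > 0")
        location = np.asarray(location, dtype=float)
        if domain is not None:
            rho = domain.mesenchyme.normalized_radius(location[None, :])[0]
            if rho >= 1.0:
                raise InputError("bead lies outside the mesenchyme")
            for curve in domain.epithelia:
                if curve.contains(location[None, :])[0]:
                    raise InputError("bead lies inside the epithelium")
        src = {"kind": "bead", "location": location, "rate": float(rate),
               "radius": float(radius)}
    else:
        src = {"kind": "uniform", "rate": float(rate)}
    new = ModelSpec(model.variant, model.params, model.readout_exponents)
    existing = getattr(model, "extra_sources", ())
    object.__setattr__(new, "extra_sources", existing + (src,))
    return new
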