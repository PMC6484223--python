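"""Quantitative comparison of predicted signalling against measured
growth fields: normalised profiles C and E, the boundary-integral
deviation Delta, its sum over frames Delta_g, log-uniform parameter
screening, and model ranking."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InputError
from .rd_models import ModelSpec, ParameterSet

__all__ = [
    "DeviationResult",
    "normalize_signal",
    "normalize_growth",
    "deviation",
    "global_deviation",
    "sample_parameters",
    "screen_models",
    "DEFAULT_RANGES",
]

# log-uniform screening ranges: two decades either side of the fixture
# Turing baseline for each kinetic constant (diffusivities are screened
# through D_R with the D_L/D_R ratio kept >= 10 for T1/T5)
DEFAULT_RANGES = {
    "rho_R": (1e-3, 1e1),
    "rho_L": (1e-2, 1e2),
    "delta_R": (1e-2, 1e2),
    "delta_L": (1e-4, 1e0),
    "mu": (1e-2, 1e2),
    "v": (1e-2, 1e2),
    "D_R": (1e-1, 1e1),
}


@dataclass
class DeviationResult:
    """Per-frame and global deviations over a collection of parameter
    sets, with the argmin sets."""

    per_frame: dict  # frame key -> array of Delta per parameter set
    global_: np.ndarray  # Delta_g per parameter set
    best_per_frame: dict  # frame key -> index of argmin set
    best_global: int


def normalize_signal(profile) -> np.ndarray:
    """C = R^m L^n / max over the interface; max(C) = 1."""
    values = np.asarray(getattr(profile, "values", profile), dtype=float)
    peak = values.max(initial=0.0)
    if peak <= 0:
        raise InputError("all-zero signal profile: normalisation undefined")
    return values / peak


def normalize_growth(field) -> np.ndarray:
    """E = |v| / max over the interface of |v|."""
    mags = np.asarray(getattr(field, "magnitudes", field), dtype=float)
    peak = mags.max(initial=0.0)
    if peak <= 0:
        raise InputError("all-zero growth field: normalisation undefined")
    return mags / peak


def deviation(C: np.ndarray, E: np.ndarray, interface: np.ndarray) -> float:
    """Delta = sqrt( integral over the interface of (C - E)^2 ds ),
    trapezoidal quadrature on the common arc-length grid."""
    C = np.asarray(C, dtype=float)
    E = np.asarray(E, dtype=float)
    s = np.asarray(interface, dtype=float)
    if C.shape != E.shape or C.shape != s.shape:
        raise InputError("C, E and the arc grid must share one shape")
    return float(np.sqrt(np.trapezoid((C - E) ** 2, s)))


def global_deviation(per_frame) -> float | np.ndarray:
    """Delta_g = sum over frames of Delta (same parameter sets on every
    frame)."""
    if isinstance(per_frame, dict):
        arrays = [np.asarray(v, dtype=float) for v in per_frame.values()]
        if not arrays:
            raise InputError("no frames supplied")
        shape = arrays[0].shape
        if any(a.shape != shape for a in arrays):
            raise InputError("every frame must cover the same parameter sets")
        return np.sum(arrays, axis=0)
    return np.sum([np.asarray(v, dtype=float) for v in per_frame], axis=0)


def sample_parameters(ranges: dict, n_sets: int, seed: int = 0,
                      base: ParameterSet | None = None) -> list[ParameterSet]:
    """Draw ``n_sets`` parameter sets log-uniformly: each named parameter
    as 10^U(log10 lo, log10 hi); unnamed parameters keep the ``base``
    values."""
    for name, (lo, hi) in ranges.items():
        if lo <= 0 or hi <= lo:
            raise InputError(f"range for {name} must satisfy 0 < lo < hi")
    if base is None:
        base = ParameterSet()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sets):
        draws = {name: float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
                 for name, (lo, hi) in ranges.items()}
        if "D_L" not in draws and "D_R" in draws:
            draws["D_L"] = draws["D_R"] * (base.D_L / base.D_R)
        out.append(replace(base, **draws))
    return out


def parameters_to_tsv(sets: list[ParameterSet], path, seed: int | None = None):
    rows = [p.to_dict() for p in sets]
    df = pd.DataFrame(rows)
    if seed is not None:
        df["seed"] = seed
    df.to_csv(path, sep="\t", index=False)


def parameters_from_tsv(path) -> list[ParameterSet]:
    df = pd.read_csv(path, sep="\t")
    df = df.drop(columns=[c for c in ("seed",) if c in df])
    fields = set(ParameterSet.__dataclass_fields__)
    return [ParameterSet(**{k: (int(v) if k in ("m", "n") else float(v))
                            for k, v in row.items() if k in fields})
            for row in df.to_dict("records")]


def screen_models(variants, frames, param_sets, *, target_h: float = 2.0,
                  n_samples: int = 400, seed: int = 0, tol: float = 1e-5,
                  smooth_arc: float = 0.0,
                  solver_kwargs: dict | None = None):
    """Rank model variants by minimal deviation against measured growth.

    Parameters
    ----------
    variants:
        Iterable of variant names ('T1'..'T5').
    frames:
        List of ``(domain, E_values)`` pairs: a TwoLayerDomain per time
        point and the normalised (or raw) growth magnitudes, either an
        array matching the interface sampling or a callable of arc
        positions.
    param_sets:
        Shared list of ParameterSet drawn once and reused across
        variants and frames.

    ``smooth_arc`` > 0 applies a periodic moving average of that arc
    length to every signalling profile before normalisation (suppresses
    sub-grid noise on screening meshes coarser than the reaction scale).

    Returns
    -------
    (table, summary, result_by_variant): a tidy ``pandas.DataFrame`` with
    one row per (variant, set, frame), a ranking summary, and a dict
    variant -> DeviationResult. Unconverged solves are recorded as NaN
    and excluded from minima.
    """
    from .fem_solver import Operators, signal_on_interface, solve_steady
    from .geometry import build_mesh

    solver_kwargs = solver_kwargs or {}
    meshes, ops_list = [], []
    for domain, _ in frames:
        mesh = build_mesh(domain, target_h=target_h)
        meshes.append(mesh)
        ops_list.append(Operators(mesh))

    rows = []
    results = {}
    for variant in variants:
        per_frame = {i: np.full(len(param_sets), np.nan) for i in range(len(frames))}
        n_unconverged = 0
        for j, params in enumerate(param_sets):
            model = ModelSpec(variant, params)
            for i, ((_domain, E_spec), mesh, ops) in enumerate(
                    zip(frames, meshes, ops_list)):
                try:
                    state = solve_steady(model, ops, seed=seed, tol=tol,
                                         **solver_kwargs)
                except Exception:
                    n_unconverged += 1
                    continue
                if not state.converged:
                    n_unconverged += 1
                    continue
                prof = signal_on_interface(state, mesh, n_samples=n_samples,
                                           model=model)
                vals = prof.values
                if smooth_arc > 0:
                    from scipy.ndimage import uniform_filter1d
                    ds = prof.total_length / len(vals)
                    vals = uniform_filter1d(vals, max(1, int(smooth_arc / ds)),
                                            mode="wrap")
                try:
                    C = normalize_signal(vals)
                except InputError:
                    n_unconverged += 1
                    continue
                E_vals = (E_spec(prof.arc_positions) if callable(E_spec)
                          else np.asarray(E_spec, dtype=float))
                E = normalize_growth(E_vals)
                d = deviation(C, E, prof.arc_positions)
                per_frame[i][j] = d
                rows.append({"variant": variant, "set": j, "frame": i, "delta": d})
        valid = ~np.any([np.isnan(per_frame[i]) for i in per_frame], axis=0)
        dg = np.where(valid, np.sum([per_frame[i] for i in per_frame], axis=0), np.nan)
        best_global = int(np.nanargmin(dg)) if np.any(valid) else -1
        results[variant] = DeviationResult(
            per_frame=per_frame, global_=dg,
            best_per_frame={i: (int(np.nanargmin(per_frame[i]))
                                if np.any(~np.isnan(per_frame[i])) else -1)
                            for i in per_frame},
            best_global=best_global)
        results[variant].n_unconverged = n_unconverged

    table = pd.DataFrame(rows)
    ranking = sorted(results, key=lambda v: (np.nanmin(results[v].global_)
                                             if np.any(~np.isnan(results[v].global_))
                                             else np.inf))
    summary = pd.DataFrame({
        "variant": ranking,
        "min_delta_g": [float(np.nanmin(results[v].global_)) for v in ranking],
        "best_set": [results[v].best_global for v in ranking],
        "n_unconverged": [results[v].n_unconverged for v in ranking],
    })
    return table, summary, results
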