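"""Canonical simulation scenarios shared by the CLI, the test suite and
the acceptance script: fixture domains, growth laws, and frame
generators for the recovery experiments."""

from __future__ import annotations

import numpy as np

from .branching_sim import GrowthLaw
from .geometry import TwoLayerDomain, mesenchyme_ellipse
from .rd_models import ModelSpec
from .synthetic_data import ShapeSpec, fixture_parameters, make_bud_shape


def two_bud_shape(seed: int = 0):
    """The length-scale-100 two-bud epithelium used for convergence and
    recovery studies (overall extent ~100 length units)."""
    spec = ShapeSpec(base=(32.0, 18.0),
                     buds=((0.55, 14.0, 0.38), (2.55, 14.0, 0.38)),
                     seed=seed)
    return make_bud_shape(spec)


def two_bud_domain(alpha: float = 3.0, seed: int = 0) -> TwoLayerDomain:
    shape = two_bud_shape(seed)
    return TwoLayerDomain((shape,), mesenchyme_ellipse(shape, alpha=alpha))


SINGLE_BUD_SIM_KWARGS = dict(target_h=1.0, solver_tol=1e-5,
                             profile_smooth_arc=3.0,
                             curvature_threshold=0.10, min_separation=8.0)


def single_bud_scenario(variant: str = "T1"):
    """Single-bud init whose circumference spans ~3 pattern wavelengths:
    the first patterning event localises three signalling peaks
    (trifurcation) and continued growth adds a fourth (bifurcation)."""
    shape = make_bud_shape(ShapeSpec(base=(12.0, 10.5),
                                     buds=((np.pi / 2, 3.0, 0.6),)))
    domain = TwoLayerDomain((shape,), mesenchyme_ellipse(shape, alpha=3.0))
    model = ModelSpec(variant, fixture_parameters()["T1"])
    law = GrowthLaw(v_g=0.04, K_g=100.0, h_g=2.0)
    return domain, law, model


def smooth_perturbation_init(model: ModelSpec):
    """Deterministic smooth perturbation of the homogeneous steady state
    (mesh-independent, so refinement studies converge into the same
    attractor)."""
    from .rd_models import steady_state_wellmixed

    ss = steady_state_wellmixed(model)

    def init(pts, species):
        base = {"R": ss[0], "L": ss[1]}.get(species, ss[-1])
        g = (np.cos(0.08 * pts[:, 0]) * np.cos(0.11 * pts[:, 1])
             + 0.5 * np.sin(0.05 * pts[:, 0] + 1.0))
        return base * (1 + 1e-3 * g)

    return init


def recovery_frames(seed: int = 0, t_end: float = 190.0, n_points: int = 400,
                    K_g: float = 140.0):
    """Ground-truth frames for the model-recovery experiment: a short
    free-boundary run of the fixture Turing model provides consecutive
    shapes, and the measured growth field between them (outward normal
    displacements, inward zeroed) plays the role of the experimental E.

    ``K_g`` sets the growth response threshold of the generating movie
    (placed above the median signal so the growth field is sharply
    localised, as in measured data).

    Returns a list of (TwoLayerDomain, E_interpolator) pairs.
    """
    from .branching_sim import simulate_branching
    from .image_pipeline import displacement_field, growth_field

    domain, law, model = single_bud_scenario("T1")
    law = GrowthLaw(v_g=law.v_g, K_g=K_g, h_g=law.h_g)
    shapes, _log, _tips = simulate_branching(
        model, domain, law, t_end=t_end, remesh_every=10, seed=seed,
        **SINGLE_BUD_SIM_KWARGS)
    frames = []
    for i in range(1, min(3, len(shapes) - 1)):
        f0 = shapes[i][1].epithelium
        f1 = shapes[i + 1][1].epithelium
        base, vecs, mags, arcs = displacement_field(f0, f1, n_points=n_points)
        gf = growth_field((base, vecs, mags, arcs))
        dom_i = TwoLayerDomain((f0,), mesenchyme_ellipse(f0, alpha=3.0))

        def E_fn(s, arcs=arcs, mags=gf.magnitudes, period=f0.total_length):
            return np.interp(s, arcs, mags, period=period)

        frames.append((dom_i, E_fn))
    return frames


def recovery_ranges(decades: float = 1.0):
    """Log-uniform screening ranges: ``decades`` decades either side of
    the fixture Turing baseline for the kinetic constants; the receptor
    diffusivity is bounded below at half the baseline (the spatial
    discretisation used by the screens cannot resolve receptor boundary
    layers below that scale)."""
    base = fixture_parameters()["T1"]
    f = 10.0 ** decades
    out = {k: (getattr(base, k) / f, getattr(base, k) * f)
           for k in ("rho_R", "rho_L", "delta_R", "delta_L", "mu", "v")}
    out["D_R"] = (base.D_R / 2, base.D_R * f)
    return out


def synthetic_growth_profile(arc_positions: np.ndarray, total_length: float,
                             centres=(0.18, 0.68), width: float = 0.045):
    """Fixed synthetic growth-field magnitudes on an interface arc grid:
    Gaussian bumps at fractional arc positions (used as the measured
    field E in convergence studies)."""
    s = np.asarray(arc_positions, dtype=float) / total_length
    out = np.zeros_like(s)
    for c in centres:
        d = np.minimum(np.abs(s - c), 1.0 - np.abs(s - c))
        out += np.exp(-0.5 * (d / width) ** 2)
    return out
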