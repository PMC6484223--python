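"""Deterministic generators for every input the pipeline needs: parametric
bud shapes, time-lapse sequences with ground-truth growth fields,
rasterised noisy masks with distractor blobs, Poisson-disk tip clouds,
and frozen fixture parameter sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as _sk_polygon

from .errors import GeometryError, InputError
from .geometry import BoundaryCurve
from .rd_models import ModelSpec, ParameterSet

__all__ = [
    "ShapeSpec",
    "GrowthSpec",
    "TimeLapse",
    "make_bud_shape",
    "make_timelapse",
    "rasterize",
    "mask_to_world",
    "make_tip_cloud",
    "fixture_parameters",
    "fixture_model",
    "two_bud_domain_curves",
]


@dataclass(frozen=True)
class ShapeSpec:
    """Base ellipse radially perturbed by Gaussian bumps.

    ``buds`` is a list of (angular position [rad], amplitude, angular
    width [rad]); ``stalk`` an optional angular interval marking the
    stalk."""

    base: tuple[float, float] = (30.0, 18.0)
    buds: tuple = ()
    stalk: tuple[float, float] | None = None
    seed: int = 0
    n_points: int = 400

    def __post_init__(self):
        for pos, amp, width in self.buds:
            if amp < 0:
                raise InputError("bud amplitudes must be >= 0")
            if width <= 0:
                raise InputError("bud widths must be > 0")


@dataclass(frozen=True)
class GrowthSpec:
    """Localised outward growth: Gaussian arc-profiles centred at
    ``growth_centres`` (arc-length positions), per-frame advance
    ``rates`` (length/frame) and arc-length ``widths``."""

    growth_centres: tuple
    rates: tuple
    widths: tuple
    n_frames: int = 4
    frame_dt: float = 2.0

    def __post_init__(self):
        if any(r < 0 for r in self.rates):
            raise InputError("growth rates must be >= 0")
        if self.n_frames < 2:
            raise InputError("need at least one frame pair")


@dataclass
class TimeLapse:
    """Frames of epithelial boundaries with timestamps (hours)."""

    frames: list
    timestamps: np.ndarray
    pixel_size: float = 1.0
    ground_truth: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(np.diff(self.timestamps) <= 0):
            raise InputError("timestamps must be strictly increasing")

    def to_json(self, path):
        import json

        payload = {"pixel_size": self.pixel_size,
                   "timestamps": np.asarray(self.timestamps).tolist(),
                   "frames": [f.points.tolist() for f in self.frames]}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TimeLapse":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        return cls(frames=[BoundaryCurve(np.asarray(p))
                           for p in payload["frames"]],
                   timestamps=np.asarray(payload["timestamps"], dtype=float),
                   pixel_size=float(payload.get("pixel_size", 1.0)))

    def pairs(self, spacing_hours: float = 2.0):
        """Frame-index pairs separated by (at least) ``spacing_hours``."""
        out = []
        i = 0
        while i < len(self.frames) - 1:
            j = i + 1
            while (j < len(self.frames)
                   and self.timestamps[j] - self.timestamps[i]
                   < spacing_hours - 1e-9):
                j += 1
            if j >= len(self.frames):
                break
            out.append((i, j))
            i = j
        return out


def make_bud_shape(spec: ShapeSpec) -> BoundaryCurve:
    """Smooth closed curve: base ellipse plus Gaussian bumps along the
    outward normal direction."""
    a, b = spec.base
    th = np.linspace(0, 2 * np.pi, spec.n_points, endpoint=False)
    x0, y0 = a * np.cos(th), b * np.sin(th)
    nx, ny = b * np.cos(th), a * np.sin(th)  # outward normal of the ellipse
    nn = np.hypot(nx, ny)
    nx, ny = nx / nn, ny / nn
    bump = np.zeros_like(th)
    for pos, amp, width in spec.buds:
        d = np.angle(np.exp(1j * (th - pos)))  # wrapped angular distance
        bump += amp * np.exp(-0.5 * (d / width) ** 2)
    pts = np.column_stack([x0 + bump * nx, y0 + bump * ny])
    stalk_interval = None
    if spec.stalk is not None:
        t0, t1 = spec.stalk
        curve_tmp = BoundaryCurve(pts)
        s = curve_tmp.arc_positions
        i0 = int(np.argmin(np.abs(np.angle(np.exp(1j * (th - t0))))))
        i1 = int(np.argmin(np.abs(np.angle(np.exp(1j * (th - t1))))))
        stalk_interval = (float(s[i0]), float(s[i1]))
    try:
        return BoundaryCurve(pts, stalk_interval=stalk_interval)
    except GeometryError as exc:
        raise GeometryError(
            "bud shape self-intersects; reduce bud amplitudes") from exc


def make_timelapse(shape: BoundaryCurve, growth: GrowthSpec) -> TimeLapse:
    """Advance the boundary along outward normals by the Gaussian
    arc-profiles of the growth spec; ground-truth per-point magnitudes
    (at the earlier frame's vertices) are stored per frame pair."""
    frames = [shape]
    truth = []
    cur = shape
    for _ in range(growth.n_frames - 1):
        s = cur.arc_positions
        total = cur.total_length
        mag = np.zeros(len(s))
        for centre, rate, width in zip(growth.growth_centres, growth.rates,
                                       growth.widths):
            d = np.abs(s - centre)
            d = np.minimum(d, total - d)  # wraparound arc distance
            mag += rate * np.exp(-0.5 * (d / width) ** 2)
        normals = cur.outward_normals()
        new_pts = cur.points + mag[:, None] * normals
        try:
            nxt = BoundaryCurve(new_pts, stalk_interval=cur.stalk_interval)
        except GeometryError as exc:
            raise GeometryError("growth produced a self-intersecting "
                                "boundary; reduce rates") from exc
        truth.append({"base_points": cur.points.copy(), "magnitudes": mag,
                      "arc_positions": s.copy()})
        frames.append(nxt)
        cur = nxt
    ts = np.arange(growth.n_frames) * growth.frame_dt
    return TimeLapse(frames=frames, timestamps=ts, ground_truth=truth)


def rasterize(curve: BoundaryCurve, resolution: float = 1.0,
              noise_sigma: float = 0.0, seed: int = 0,
              pad: int = 10, distractors: int = 0) -> tuple[np.ndarray, dict]:
    """Filled-polygon grayscale image of the curve (row 0 is max y).

    Returns (image, meta); ``mask_to_world`` converts (row, col) back to
    world coordinates. Distractor blobs (each < 10% of the main area)
    exercise largest-component selection.
    """
    if resolution <= 0:
        raise InputError("resolution must be positive")
    rng = np.random.default_rng(seed)
    pts = curve.points
    x0, y0 = pts.min(axis=0) - pad / resolution
    x1, y1 = pts.max(axis=0) + pad / resolution
    W = int(np.ceil((x1 - x0) * resolution)) + 1
    H = int(np.ceil((y1 - y0) * resolution)) + 1
    rows = (y1 - pts[:, 1]) * resolution
    cols = (pts[:, 0] - x0) * resolution
    img = np.zeros((H, W), dtype=float)
    rr, cc = _sk_polygon(rows, cols, shape=img.shape)
    img[rr, cc] = 1.0
    main_area = len(rr)

    for _ in range(distractors):
        r_blob = max(1.0, np.sqrt(0.05 * main_area / np.pi))
        for _try in range(50):
            cr = rng.uniform(0, H)
            cz = rng.uniform(0, W)
            yy, xx = np.ogrid[:H, :W]
            disc = (yy - cr) ** 2 + (xx - cz) ** 2 < r_blob ** 2
            if not np.any(disc & (img > 0.5)):
                img[disc] = 1.0
                break
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    meta = {"x0": float(x0), "y1": float(y1), "resolution": float(resolution)}
    return img, meta


def mask_to_world(rows_cols: np.ndarray, meta: dict) -> np.ndarray:
    """Convert (row, col) image coordinates to world (x, y), y up."""
    rc = np.asarray(rows_cols, dtype=float)
    res = meta["resolution"]
    x = rc[:, 1] / res + meta["x0"]
    y = meta["y1"] - rc[:, 0] / res
    return np.column_stack([x, y])


def _ellipsoid_surface_points(semi_axes, n, rng):
    """Approximately area-uniform random points on an ellipsoid surface
    (rejection from the sphere parametrisation against the area factor)."""
    a, b, c = semi_axes
    out: list[np.ndarray] = []
    while len(out) < n:
        u = rng.normal(size=(4 * n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        p = u * np.array([a, b, c])
        g = np.sqrt((u[:, 0] * b * c) ** 2 + (u[:, 1] * a * c) ** 2
                    + (u[:, 2] * a * b) ** 2)
        keep = rng.random(len(u)) < g / g.max()
        out.extend(p[keep])
    return np.asarray(out[:n])


def make_tip_cloud(n_target: int, d_min: float, surface=(300.0, 220.0, 160.0),
                   seed: int = 0, max_attempts: int | None = None):
    """Poisson-disk (dart-throwing) sampling on an ellipsoid surface:
    pairwise distances >= d_min. Returns (points, saturated); fewer
    than ``n_target`` points with ``saturated=True`` when packing is
    infeasible."""
    if d_min <= 0:
        raise InputError("d_min must be positive")
    rng = np.random.default_rng(seed)
    semi = tuple(float(s) for s in surface)
    if max_attempts is None:
        max_attempts = 60 * n_target
    kept: list[np.ndarray] = []
    candidates = _ellipsoid_surface_points(semi, max_attempts, rng)
    # spatial hash: cells of size d_min, check the 27 neighbouring cells
    cell = {}
    inv = 1.0 / d_min
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1)]
    for p in candidates:
        if len(kept) >= n_target:
            break
        key = tuple((p * inv).astype(int))
        ok = True
        for off in offsets:
            nb = (key[0] + off[0], key[1] + off[1], key[2] + off[2])
            for q in cell.get(nb, ()):
                if np.dot(p - q, p - q) < d_min * d_min:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            kept.append(p)
            cell.setdefault(key, []).append(p)
    saturated = len(kept) < n_target
    return np.asarray(kept), saturated


# ---------------------------------------------------------------------------
# fixture parameter sets (frozen from a seeded stability-analysis scan)

_FIXTURES = {
    # Turing-positive baseline: pattern wavelength ~26 length units,
    # suited to domains of typical length scale 100
    "T1": ParameterSet(D_R=4.0, D_L=80.0, rho_R=0.1, rho_L=0.9,
                       delta_R=1.0, delta_L=0.01, mu=1.0, v=3.0, m=2, n=1),
    # finer pattern (wavelength ~13) for small unit-test domains
    "T1_fine": ParameterSet(D_R=1.0, D_L=20.0, rho_R=0.1, rho_L=0.9,
                            delta_R=1.0, delta_L=0.01, mu=1.0, v=3.0, m=2, n=1),
    # rate-scaled T1 (all kinetic rates x 1/4, transport unchanged): same
    # steady-state family with a coarser feature scale, used for mesh
    # convergence studies where the deviation must be resolution-stable
    "T1_smooth": ParameterSet(D_R=16.0, D_L=320.0, rho_R=0.025, rho_L=0.225,
                              delta_R=0.25, delta_L=0.0025, mu=0.25, v=0.75,
                              m=2, n=1),
    # T5: T1 kinetics at reduced constitutive ligand production plus an
    # active short-range second-ligand feedback that boosts ligand
    # production near signalling tips (prevents depletion between
    # approaching tips)
    "T5": ParameterSet(D_R=4.0, D_L=80.0, rho_R=0.1, rho_L=0.45,
                       delta_R=1.0, delta_L=0.01, mu=1.0, v=3.0, m=2, n=1,
                       b_1=0.05, delta_L1=0.5, gamma=10.0, K_fb=10.0,
                       D_L1=2.0),
}


def fixture_parameters() -> dict[str, ParameterSet]:
    """Named frozen parameter sets: a stability-verified Turing set for
    T1 (whose T2/T3/T4 degenerations are stability-negative) and a T5
    set with active feedback."""
    return dict(_FIXTURES)


def fixture_model(variant: str = "T1", fine: bool = False) -> ModelSpec:
    if variant == "T5":
        return ModelSpec("T5", _FIXTURES["T5"])
    base = _FIXTURES["T1_fine" if fine else "T1"]
    return ModelSpec(variant, base)


def two_bud_domain_curves(l0: float, bud_length: float = 25.0,
                          bud_width: float = 10.0, n_points: int = 200):
    """Two opposing elliptical buds whose facing tips are ``l0`` apart
    (centred on the x axis, tips pointing at each other)."""
    if l0 <= 0:
        raise InputError("l0 must be positive")
    th = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    ell = np.column_stack([bud_length * np.cos(th), bud_width * np.sin(th)])
    off = l0 / 2 + bud_length
    left = BoundaryCurve(ell + np.array([-off, 0.0]))
    right = BoundaryCurve(ell + np.array([off, 0.0]))
    return left, right
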