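"""Boundary extraction from mask images and field computation between
consecutive frames: displacement fields by normal-ray casting, growth
fields (inward vectors zeroed), and 2D interbud minimal distances."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point
from skimage import exposure, measure

from .errors import GeometryError, InputError
from .geometry import BoundaryCurve, fit_boundary_spline

__all__ = [
    "GrowthField",
    "segment_epithelium",
    "extract_border",
    "displacement_field",
    "growth_field",
    "interbud_min_distance",
]


@dataclass
class GrowthField:
    """Outward-only boundary displacement: vectors are zero or aligned
    with the outward normal of their base point."""

    base_points: np.ndarray
    vectors: np.ndarray
    magnitudes: np.ndarray
    arc_positions: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.magnitudes < 0):
            raise InputError("growth magnitudes must be >= 0")


def segment_epithelium(image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Contrast-stretch, threshold, and keep the largest connected
    component."""
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise InputError("empty image")
    lo, hi = np.percentile(img, (1, 99))
    if hi > lo:
        img = exposure.rescale_intensity(img, in_range=(lo, hi),
                                         out_range=(0.0, 1.0))
    mask = img > threshold
    if not mask.any():
        raise InputError(f"empty mask after thresholding at {threshold}")
    labels = measure.label(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def extract_border(mask: np.ndarray) -> np.ndarray:
    """Ordered, closed, counter-clockwise outer boundary of the single
    foreground component, in (row, col) pixel coordinates (subpixel)."""
    mask = np.asarray(mask, dtype=bool)
    n_comp = measure.label(mask).max()
    if n_comp > 1:
        raise InputError("mask has multiple components; segment first")
    if n_comp == 0:
        raise InputError("mask is empty")
    if mask.sum() < 4:
        raise GeometryError("foreground too small to trace a boundary loop")
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise GeometryError("no boundary contour found")
    outer = max(contours, key=len) - 1.0  # undo the pad
    if len(outer) < 4:
        raise GeometryError("degenerate boundary loop")
    if np.allclose(outer[0], outer[-1]):
        outer = outer[:-1]
    return outer


def _ray_polygon_hits(origins, directions, polygon_pts):
    """Smallest positive ray parameter t per origin for rays
    origin + t*direction against all polygon segments; inf when no hit."""
    a = polygon_pts
    b = np.roll(polygon_pts, -1, axis=0)
    e = b - a  # (M, 2)
    o = origins[:, None, :]  # (N,1,2)
    d = directions[:, None, :]
    ao = a[None, :, :] - o  # (N,M,2)
    denom = d[..., 0] * e[None, :, 1] - d[..., 1] * e[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ao[..., 0] * e[None, :, 1] - ao[..., 1] * e[None, :, 0]) / denom
        s = (ao[..., 0] * d[..., 1] - ao[..., 1] * d[..., 0]) / denom
    # t >= 0 (within rounding) so a base point lying exactly on the
    # target curve yields zero displacement rather than a miss
    valid = (np.abs(denom) > 1e-14) & (s >= 0.0) & (s <= 1.0) & (t > -1e-9)
    t = np.where(valid, np.maximum(t, 0.0), np.inf)
    return t.min(axis=1)


def displacement_field(curve_t: BoundaryCurve, curve_next: BoundaryCurve,
                       n_points: int = 400, max_ray: float | None = None):
    """Signed normal displacements from ``curve_t`` to ``curve_next``.

    At ``n_points`` uniformly arc-spaced base points, the outward normal
    ray is cast; the first intersection with the next frame's boundary
    gives a positive (outward) vector. If the outward ray misses within
    ``max_ray``, the inward ray is tried and the result marked negative
    (shrinkage). Points where neither ray hits are flagged missing (NaN
    magnitude).

    Returns (base_points, vectors, signed_magnitudes, arc_positions).
    """
    if max_ray is None:
        bb = curve_t.points.max(axis=0) - curve_t.points.min(axis=0)
        max_ray = 0.2 * float(np.hypot(*bb))
    total = curve_t.total_length
    s = np.linspace(0.0, total, n_points, endpoint=False)
    if curve_t.has_spline:
        t_par = s / total
        base = curve_t.eval_spline(t_par)
        d = curve_t.eval_spline(t_par, nu=1)
        nrm = np.linalg.norm(d, axis=1, keepdims=True)
        if np.any(nrm < 1e-12):
            raise GeometryError("degenerate spline tangent (duplicate points?)")
        tang = d / nrm
        normals = np.column_stack([tang[:, 1], -tang[:, 0]])
    else:
        base = curve_t.points_at(s)
        tmp = BoundaryCurve(base)
        normals = tmp.outward_normals()
        base = tmp.points

    target = curve_next.points
    t_out = _ray_polygon_hits(base, normals, target)
    t_in = _ray_polygon_hits(base, -normals, target)

    mags = np.full(n_points, np.nan)
    vectors = np.zeros((n_points, 2))
    hit_out = t_out <= max_ray
    hit_in = (~hit_out) & (t_in <= max_ray)
    mags[hit_out] = t_out[hit_out]
    vectors[hit_out] = normals[hit_out] * t_out[hit_out, None]
    mags[hit_in] = -t_in[hit_in]
    vectors[hit_in] = -normals[hit_in] * t_in[hit_in, None]
    return base, vectors, mags, s


def growth_field(displacements) -> GrowthField:
    """Zero all inward (negative) and missing displacement vectors;
    keep outward vectors unchanged."""
    base, vectors, mags, arc = displacements
    mags = np.asarray(mags, dtype=float)
    out_mags = np.where(np.isnan(mags) | (mags < 0), 0.0, mags)
    out_vecs = np.where(out_mags[:, None] > 0, vectors, 0.0)
    return GrowthField(base_points=np.asarray(base), vectors=out_vecs,
                       magnitudes=out_mags, arc_positions=np.asarray(arc))


def interbud_min_distance(buds, image_extent) -> dict:
    """Per-bud minimal boundary-to-boundary distance to any other bud.

    For every boundary point of every bud the minimal distance to all
    other buds' borders is computed; points closer to the image edge
    than to any other bud are discarded. Returns per-bud retained
    point distances, per-bud minima, and the overall minimum.

    ``image_extent`` is ((x0, y0), (x1, y1)).
    """
    if len(buds) < 2:
        raise InputError("need at least two buds")
    (x0, y0), (x1, y1) = image_extent
    rings = [LineString(np.vstack([b.points, b.points[:1]])) for b in buds]
    result = {"per_bud": [], "per_bud_min": [], "overall_min": None}
    overall = np.inf
    for i, bud in enumerate(buds):
        others = [rings[j] for j in range(len(buds)) if j != i]
        pts = bud.points
        d_other = np.array([min(r.distance(Point(p)) for r in others)
                            for p in pts])
        d_edge = np.minimum.reduce([pts[:, 0] - x0, x1 - pts[:, 0],
                                    pts[:, 1] - y0, y1 - pts[:, 1]])
        keep = d_other <= d_edge
        kept = d_other[keep]
        result["per_bud"].append({"distances": kept, "n_discarded":
                                  int(np.sum(~keep))})
        if len(kept):
            m = float(kept.min())
            result["per_bud_min"].append(m)
            overall = min(overall, m)
        else:
            result["per_bud_min"].append(None)
    result["overall_min"] = None if np.isinf(overall) else float(overall)
    return result


def border_to_curve(border_rc: np.ndarray, meta: dict | None = None,
                    smooth: bool = True, n_control: int | None = None) -> BoundaryCurve:
    """Convert a traced (row, col) border to a world-coordinate
    BoundaryCurve (y up), optionally spline-smoothed."""
    if meta is not None:
        from .synthetic_data import mask_to_world
        pts = mask_to_world(border_rc, meta)
    else:
        pts = np.column_stack([border_rc[:, 1], -border_rc[:, 0]])
    # drop consecutive duplicates from contour tracing
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    pts = pts[keep]
    if smooth:
        return fit_boundary_spline(pts, n_control=n_control)
    return BoundaryCurve(pts)
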