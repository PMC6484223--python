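"""Two-layer computational domains: epithelial boundary curves, the
moment-derived mesenchymal ellipse, and subdomain-labelled triangulations.

Coordinates are continuous 2D Cartesian (y up); closed curves are stored
counter-clockwise so that outward normals point away from the enclosed
region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy.interpolate import BSpline
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import LineString

from .errors import GeometryError, InputError

EPITHELIUM = 1
MESENCHYME = 2

EDGE_INTERFACE = "interface"
EDGE_OUTER = "outer"
EDGE_STALK = "stalk"

__all__ = [
    "BoundaryCurve",
    "Ellipse2D",
    "TwoLayerDomain",
    "Mesh",
    "fit_boundary_spline",
    "mesenchyme_ellipse",
    "remove_stalk",
    "build_mesh",
    "polygon_moments",
    "EPITHELIUM",
    "MESENCHYME",
]


# ---------------------------------------------------------------------------
# polygon helpers


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_moments(points: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid and per-unit-mass central second moments of the
    uniformly filled polygon (Green's theorem; exact for polygons).

    Returns ``(area, centroid, M)`` with ``M = [[xx, xy], [xy, yy]]``.
    """
    points = np.asarray(points, dtype=float)
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * float(np.sum(cross))
    if abs(area) < 1e-12:
        raise GeometryError("polygon has (near) zero area")
    cx = float(np.sum((x + xn) * cross) / (6.0 * area))
    cy = float(np.sum((y + yn) * cross) / (6.0 * area))
    # second moments about the origin, then shift to the centroid
    ixx = float(np.sum((x * x + x * xn + xn * xn) * cross) / 12.0)
    iyy = float(np.sum((y * y + y * yn + yn * yn) * cross) / 12.0)
    ixy = float(np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0)
    xx = ixx / area - cx * cx
    yy = iyy / area - cy * cy
    xy = ixy / area - cx * cy
    return area, np.array([cx, cy]), np.array([[xx, xy], [xy, yy]])


def _is_simple_polygon(points: np.ndarray) -> bool:
    ring = np.vstack([points, points[:1]])
    return LineString(ring).is_simple


# ---------------------------------------------------------------------------
# periodic least-squares B-splines


def _periodic_design_matrix(t: np.ndarray, n_control: int, degree: int):
    """Design matrix of the uniform periodic B-spline basis on [0, 1)."""
    k = degree
    knots = np.arange(-k, n_control + k + 1, dtype=float) / n_control
    A = BSpline.design_matrix(t, knots, k).toarray()  # (N, n_control + k)
    folded = np.zeros((len(t), n_control))
    for j in range(n_control + k):
        folded[:, j % n_control] += A[:, j]
    return folded


def _periodic_spline_eval(coef: np.ndarray, t: np.ndarray, degree: int, nu: int = 0):
    """Evaluate (a derivative of) the periodic spline with wrapped coefficients."""
    n = len(coef)
    k = degree
    knots = np.arange(-k, n + k + 1, dtype=float) / n
    cext = coef[np.arange(n + k) % n]
    spl = BSpline(knots, cext, k)
    return spl(np.mod(t, 1.0), nu=nu)


@dataclass(frozen=True)
class BoundaryCurve:
    """Closed, simple, counter-clockwise epithelial boundary.

    ``points`` are the ordered polygon vertices; an optional periodic
    spline (``coef_x``/``coef_y``) carries a smooth representation.
    ``stalk_interval`` marks an arc-length interval [s0, s1] (wrapping
    allowed) occupied by the stalk.
    """

    points: np.ndarray
    closed: bool = True
    stalk_interval: tuple[float, float] | None = None
    spline_degree: int = 3
    coef_x: np.ndarray | None = field(default=None, repr=False)
    coef_y: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise InputError("boundary needs >= 3 two-dimensional points")
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        if np.any(seg < 1e-12):
            raise InputError("consecutive boundary points must be distinct")
        if not _is_simple_polygon(pts):
            raise GeometryError("boundary polygon is self-intersecting")
        if _signed_area(pts) < 0:  # enforce CCW orientation
            pts = pts[::-1].copy()
        object.__setattr__(self, "points", pts)

    # -- basic metrics ----------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def segment_lengths(self) -> np.ndarray:
        closed = np.vstack([self.points, self.points[:1]])
        return np.linalg.norm(np.diff(closed, axis=0), axis=1)

    @property
    def arc_positions(self) -> np.ndarray:
        """Arc-length coordinate of each vertex (first vertex at 0)."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)[:-1]])

    @property
    def total_length(self) -> float:
        return float(np.sum(self.segment_lengths))

    @property
    def area(self) -> float:
        return abs(_signed_area(self.points))

    @property
    def has_spline(self) -> bool:
        return self.coef_x is not None

    # -- spline evaluation ------------------------------------------------
    def _require_spline(self):
        if not self.has_spline:
            raise InputError("curve carries no spline; fit_boundary_spline first")

    def eval_spline(self, t: np.ndarray, nu: int = 0) -> np.ndarray:
        """Evaluate the periodic spline (or its nu-th derivative) at
        normalised parameters ``t`` in [0, 1)."""
        self._require_spline()
        x = _periodic_spline_eval(self.coef_x, t, self.spline_degree, nu)
        y = _periodic_spline_eval(self.coef_y, t, self.spline_degree, nu)
        return np.column_stack([x, y])

    def spline_points(self, n: int) -> np.ndarray:
        return self.eval_spline(np.linspace(0.0, 1.0, n, endpoint=False))

    # -- resampling & normals ---------------------------------------------
    def resample(self, n: int, offset: float = 0.0) -> "BoundaryCurve":
        """Uniform arc-length resampling to ``n`` vertices (polygon-based).
        ``offset`` shifts the start point along the arc (avoids pinning
        vertex 0 across repeated resampling)."""
        s = offset + np.linspace(0.0, self.total_length, n, endpoint=False)
        return replace(self, points=self.points_at(s), coef_x=None, coef_y=None)

    def points_at(self, s: np.ndarray) -> np.ndarray:
        """Points at arc-length coordinates ``s`` by linear interpolation
        along the polygon."""
        s = np.mod(np.asarray(s, dtype=float), self.total_length)
        knots = np.concatenate([self.arc_positions, [self.total_length]])
        closed = np.vstack([self.points, self.points[:1]])
        x = np.interp(s, knots, closed[:, 0])
        y = np.interp(s, knots, closed[:, 1])
        return np.column_stack([x, y])

    def outward_normals(self) -> np.ndarray:
        """Unit outward normals at the vertices (central differences on
        the polygon; spline derivative when available)."""
        if self.has_spline:
            t = self.arc_positions / self.total_length
            d = self.eval_spline(t, nu=1)
        else:
            nxt = np.roll(self.points, -1, axis=0)
            prv = np.roll(self.points, 1, axis=0)
            d = nxt - prv
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        tangent = d / norms
        # CCW: interior on the left, outward = tangent rotated by -90 deg
        return np.column_stack([tangent[:, 1], -tangent[:, 0]])

    def contains(self, pts: np.ndarray, radius: float = 0.0) -> np.ndarray:
        return _MplPath(self.points).contains_points(np.atleast_2d(pts), radius=radius)

    # -- serialisation ----------------------------------------------------
    def to_csv(self, path):
        np.savetxt(path, self.points, delimiter=",", header="x,y", comments="")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "BoundaryCurve":
        pts = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(points=pts, **kwargs)


@dataclass(frozen=True)
class Ellipse2D:
    """Axis-aligned-in-eigenframe ellipse given by center, semi-axes
    (r1 >= r2 > 0) and the unit first-principal-axis direction."""

    center: np.ndarray
    semi_axes: tuple[float, float]
    orientation: np.ndarray

    def __post_init__(self):
        r1, r2 = self.semi_axes
        if not (r1 >= r2 > 0):
            raise InputError("semi-axes must satisfy r1 >= r2 > 0")
        v = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise InputError("orientation must be a nonzero vector")
        object.__setattr__(self, "orientation", v / n)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    @property
    def rotation(self) -> np.ndarray:
        c, s = self.orientation
        return np.array([[c, -s], [s, c]])

    def boundary_points(self, n: int) -> np.ndarray:
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r1, r2 = self.semi_axes
        local = np.column_stack([r1 * np.cos(th), r2 * np.sin(th)])
        return local @ self.rotation.T + self.center

    def normalized_radius(self, pts: np.ndarray) -> np.ndarray:
        """1.0 on the ellipse, < 1 inside."""
        local = (np.atleast_2d(pts) - self.center) @ self.rotation
        r1, r2 = self.semi_axes
        return np.sqrt((local[:, 0] / r1) ** 2 + (local[:, 1] / r2) ** 2)

    def scaled(self, factor: float) -> "Ellipse2D":
        r1, r2 = self.semi_axes
        return Ellipse2D(self.center, (r1 * factor, r2 * factor), self.orientation)


@dataclass(frozen=True)
class TwoLayerDomain:
    """Epithelium (one or more closed curves) inside an elliptical
    mesenchyme; the interface is each epithelial boundary minus its
    stalk interval."""

    epithelia: tuple[BoundaryCurve, ...]
    mesenchyme: Ellipse2D

    def __post_init__(self):
        if isinstance(self.epithelia, BoundaryCurve):
            object.__setattr__(self, "epithelia", (self.epithelia,))
        else:
            object.__setattr__(self, "epithelia", tuple(self.epithelia))
        if not self.epithelia:
            raise InputError("need at least one epithelial curve")
        for curve in self.epithelia:
            rho = self.mesenchyme.normalized_radius(curve.points)
            if np.any(rho >= 1.0):
                raise GeometryError("epithelium is not strictly inside the mesenchyme")

    @property
    def epithelium(self) -> BoundaryCurve:
        return self.epithelia[0]

    def to_json(self, path):
        payload = {
            "epithelia": [c.points.tolist() for c in self.epithelia],
            "stalk_intervals": [c.stalk_interval for c in self.epithelia],
            "mesenchyme": {
                "center": self.mesenchyme.center.tolist(),
                "semi_axes": list(self.mesenchyme.semi_axes),
                "orientation": self.mesenchyme.orientation.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TwoLayerDomain":
        with open(path) as fh:
            payload = json.load(fh)
        curves = tuple(
            BoundaryCurve(np.asarray(p), stalk_interval=tuple(si) if si else None)
            for p, si in zip(payload["epithelia"], payload["stalk_intervals"])
        )
        m = payload["mesenchyme"]
        ell = Ellipse2D(np.asarray(m["center"]), tuple(m["semi_axes"]),
                        np.asarray(m["orientation"]))
        return cls(curves, ell)


# ---------------------------------------------------------------------------
# operations


def fit_boundary_spline(points: np.ndarray, degree: int = 3,
                        n_control: int | None = None,
                        rms_tolerance: float | None = None) -> BoundaryCurve:
    """Least-squares periodic B-spline fit to ordered closed boundary samples.

    Parameters
    ----------
    points:
        Ordered samples of a simple closed curve, shape (N, 2).
    degree:
        Spline degree (3 by default, matching cubic border fits).
    n_control:
        Number of periodic control coefficients; defaults to
        ``max(8, N // 4)`` capped at N - 1.
    rms_tolerance:
        When given, the RMS residual of the fit must not exceed it.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("points must have shape (N, 2)")
    if len(pts) < degree + 2:
        raise InputError(f"need at least degree+2={degree + 2} points")
    if not _is_simple_polygon(pts):
        raise GeometryError("input polygon self-intersects")
    if _signed_area(pts) < 0:
        pts = pts[::-1].copy()
    if n_control is None:
        n_control = min(max(8, len(pts) // 4), len(pts) - 1)
    n_control = min(n_control, len(pts) - 1)

    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = s[:-1] / s[-1]  # chord-length parameters in [0, 1)

    A = _periodic_design_matrix(t, n_control, degree)
    coef_x, *_ = np.linalg.lstsq(A, pts[:, 0], rcond=None)
    coef_y, *_ = np.linalg.lstsq(A, pts[:, 1], rcond=None)

    fitted = np.column_stack([A @ coef_x, A @ coef_y])
    rms = float(np.sqrt(np.mean(np.sum((fitted - pts) ** 2, axis=1))))
    if rms_tolerance is not None and rms > rms_tolerance:
        raise GeometryError(f"spline RMS residual {rms:.3g} exceeds {rms_tolerance:.3g}")

    # dense evaluation becomes the stored polygon so downstream polygon
    # operations see the smooth curve
    n_dense = max(4 * len(pts), 64)
    td = np.linspace(0.0, 1.0, n_dense, endpoint=False)
    xd = _periodic_spline_eval(coef_x, td, degree)
    yd = _periodic_spline_eval(coef_y, td, degree)
    dense = np.column_stack([xd, yd])
    if not _is_simple_polygon(dense):
        raise GeometryError("fitted spline self-intersects")
    return BoundaryCurve(points=dense, spline_degree=degree,
                         coef_x=coef_x, coef_y=coef_y)


def remove_stalk(curve: BoundaryCurve) -> BoundaryCurve:
    """Excise the stalk interval and re-close the curve with a straight
    chord between the cut endpoints."""
    if curve.stalk_interval is None:
        return curve
    s0, s1 = curve.stalk_interval
    total = curve.total_length
    if s0 == s1:
        return replace(curve, stalk_interval=None)
    span = (s1 - s0) % total
    if span == 0 or span >= total - 1e-9:
        raise InputError("stalk interval covers the whole curve")
    s = curve.arc_positions
    inside = ((s - s0) % total) < span  # vertices strictly in the stalk
    kept = curve.points[~inside]
    # exact cut points close the chord accurately
    p0 = curve.points_at(np.array([s0]))[0]
    p1 = curve.points_at(np.array([s1]))[0]
    order = np.argsort(((s[~inside] - s1) % total))
    ring = np.vstack([p1, kept[order], p0])
    # drop duplicates introduced when cut points coincide with vertices
    dedup = [ring[0]]
    for p in ring[1:]:
        if np.linalg.norm(p - dedup[-1]) > 1e-9:
            dedup.append(p)
    ring = np.asarray(dedup)
    if len(ring) < 3:
        raise GeometryError("stalk removal left a degenerate curve")
    return BoundaryCurve(points=ring, stalk_interval=None,
                         spline_degree=curve.spline_degree)


def mesenchyme_ellipse(epithelium: BoundaryCurve | tuple[BoundaryCurve, ...],
                       alpha: float = 3.0,
                       mode: str = "filled") -> Ellipse2D:
    """Ellipse representing the mesenchyme, from the second central
    moments of the epithelial region: semi-axes ``r_i = 2 * alpha * sqrt(lambda_i)``.

    ``mode='filled'`` uses the uniformly filled region (default);
    ``mode='boundary'`` uses uniformly spaced boundary points.
    Stalk intervals are excised before the moment computation.
    """
    if alpha <= 0:
        raise InputError("alpha must be positive")
    curves = epithelium if isinstance(epithelium, (tuple, list)) else (epithelium,)
    curves = [remove_stalk(c) for c in curves]

    if mode == "filled":
        areas, cents, mats = [], [], []
        for c in curves:
            a, cen, m = polygon_moments(c.points)
            areas.append(abs(a)), cents.append(cen), mats.append(m)
        areas = np.asarray(areas)
        w = areas / areas.sum()
        center = np.einsum("i,ij->j", w, np.asarray(cents))
        M = np.zeros((2, 2))
        for wi, cen, m in zip(w, cents, mats):
            d = cen - center
            M += wi * (m + np.outer(d, d))
    elif mode == "boundary":
        pts = np.vstack([c.resample(max(c.n_points, 256)).points for c in curves])
        center = pts.mean(axis=0)
        d = pts - center
        M = d.T @ d / len(pts)
    else:
        raise InputError(f"unknown moment mode {mode!r}")

    lam, vec = np.linalg.eigh(M)  # ascending
    lam = np.clip(lam, 0.0, None)
    r = 2.0 * alpha * np.sqrt(lam)
    if r[1] <= 0:
        raise GeometryError("degenerate epithelial region (zero second moments)")
    r2, r1 = r  # ascending -> (minor, major)
    if r2 <= 0:
        r2 = 1e-6 * r1
    return Ellipse2D(center=center, semi_axes=(float(r1), float(r2)),
                     orientation=vec[:, 1])


# ---------------------------------------------------------------------------
# meshing


@dataclass
class Mesh:
    """Conforming triangulation of a TwoLayerDomain.

    ``subdomain_labels`` holds EPITHELIUM/MESENCHYME per triangle;
    ``interface_loops`` the ordered node indices of each epithelial
    boundary (closed loops); ``boundary_edges`` maps edge label ->
    (n_edges, 2) node-index array.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    subdomain_labels: np.ndarray
    interface_loops: list[np.ndarray]
    boundary_edges: dict
    target_h: float
    stalk_node_mask: np.ndarray | None = None
    interface_arcs: list[np.ndarray] | None = None
    curve_lengths: list[float] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def min_angles(self) -> np.ndarray:
        """Smallest interior angle per triangle, degrees."""
        p = self.nodes[self.triangles]
        angles = np.empty((len(self.triangles), 3))
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.sum(a * b, axis=1) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
            angles[:, i] = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        return angles.min(axis=1)

    def median_edge_length(self) -> float:
        e = self.nodes[self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)]
        return float(np.median(np.linalg.norm(e[:, 1] - e[:, 0], axis=1)))

    def subdomain_area(self, label: int) -> float:
        return float(self.triangle_areas()[self.subdomain_labels == label].sum())

    def epithelial_node_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[np.unique(self.triangles[self.subdomain_labels == EPITHELIUM])] = True
        return mask

    def interface_arc_positions(self, loop_index: int = 0) -> np.ndarray:
        loop = self.interface_loops[loop_index]
        pts = self.nodes[loop]
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)[:-1]])

    def save_msh(self, path):
        """Gmsh v2 ASCII export."""
        with open(path, "w") as fh:
            fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
            fh.write(f"{self.n_nodes}\n")
            for i, (x, y) in enumerate(self.nodes, start=1):
                fh.write(f"{i} {x} {y} 0\n")
            fh.write("$EndNodes\n$Elements\n")
            fh.write(f"{self.n_triangles}\n")
            for i, (tri, lab) in enumerate(zip(self.triangles, self.subdomain_labels),
                                           start=1):
                a, b, c = tri + 1
                fh.write(f"{i} 2 2 {lab} {lab} {a} {b} {c}\n")
            fh.write("$EndElements\n")


def rectangle_mesh(lx: float, ly: float, h: float) -> Mesh:
    """Structured uniform triangulation of [0, lx] x [0, ly], every
    element labelled epithelial (single-layer domains for collapsed
    solves and conservation checks)."""
    if lx <= 0 or ly <= 0 or h <= 0:
        raise InputError("rectangle dimensions and h must be positive")
    nx = max(2, int(round(lx / h)) + 1)
    ny = max(2, int(round(ly / h)) + 1)
    xs = np.linspace(0, lx, nx)
    ys = np.linspace(0, ly, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * ny + j

    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:  # alternate diagonals for isotropy
                tris.append((a, b, c))
                tris.append((a, c, d))
            else:
                tris.append((a, b, d))
                tris.append((b, c, d))
    triangles = np.asarray(tris, dtype=int)
    labels = np.full(len(triangles), EPITHELIUM, dtype=int)
    # boundary loop (counter-clockwise) doubles as the interface loop
    loop = ([nid(i, 0) for i in range(nx)]
            + [nid(nx - 1, j) for j in range(1, ny)]
            + [nid(i, ny - 1) for i in range(nx - 2, -1, -1)]
            + [nid(0, j) for j in range(ny - 2, 0, -1)])
    loop = np.asarray(loop, dtype=int)
    edges = np.column_stack([loop, np.roll(loop, -1)])
    return Mesh(nodes=nodes, triangles=triangles, subdomain_labels=labels,
                interface_loops=[loop],
                boundary_edges={EDGE_OUTER: edges,
                                EDGE_INTERFACE: np.empty((0, 2), dtype=int),
                                EDGE_STALK: np.empty((0, 2), dtype=int)},
                target_h=h, stalk_node_mask=np.zeros(len(nodes), dtype=bool))


def _triangle_min_angles(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = nodes[triangles]
    angles = np.empty((len(triangles), 3))
    for i in range(3):
        a = p[:, (i + 1) % 3] - p[:, i]
        b = p[:, (i + 2) % 3] - p[:, i]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        na[na == 0] = 1e-30
        nb[nb == 0] = 1e-30
        cosang = np.sum(a * b, axis=1) / (na * nb)
        angles[:, i] = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    return angles.min(axis=1)


def _hex_lattice(bbox, h: float) -> np.ndarray:
    (x0, y0), (x1, y1) = bbox
    dy = h * np.sqrt(3) / 2
    ys = np.arange(y0, y1 + dy, dy)
    cols = []
    for j, y in enumerate(ys):
        off = 0.5 * h if j % 2 else 0.0
        xs = np.arange(x0 + off, x1 + h, h)
        cols.append(np.column_stack([xs, np.full_like(xs, y)]))
    return np.vstack(cols)


def _edge_set(triangles: np.ndarray) -> set:
    e = triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    e = np.sort(e, axis=1)
    return set(map(tuple, e))


def build_mesh(domain: TwoLayerDomain, target_h: float,
               h_far: float | None = None,
               min_angle_floor: float = 10.0,
               smooth_iters: int = 4,
               max_conformity_rounds: int = 6) -> Mesh:
    """Delaunay triangulation of the two-layer domain with the epithelial
    interfaces constrained (boundary nodes shared, interface segments
    enforced as mesh edges).

    ``h_far`` enables grading: spacing ``target_h`` near the epithelium
    growing linearly to ``h_far`` away from it (used for refined
    reference meshes where only the interface region matters).
    """
    if target_h <= 0:
        raise InputError("target_h must be positive")
    ell = domain.mesenchyme

    hb = 0.8 * target_h
    loops_pts = []
    loops_stalk = []
    loops_arcs = []
    for curve in domain.epithelia:
        n_b = max(16, int(np.ceil(curve.total_length / hb)))
        s = np.linspace(0.0, curve.total_length, n_b, endpoint=False)
        loops_pts.append(curve.points_at(s))
        loops_arcs.append(s)
        if curve.stalk_interval is not None:
            s0, s1 = curve.stalk_interval
            span = (s1 - s0) % curve.total_length
            loops_stalk.append(((s - s0) % curve.total_length) < span)
        else:
            loops_stalk.append(np.zeros(n_b, dtype=bool))

    h_out = h_far if h_far is not None else target_h
    per_out = np.pi * (3 * sum(ell.semi_axes) / 2
                       - np.sqrt((3 * ell.semi_axes[0] + ell.semi_axes[1])
                                 * (ell.semi_axes[0] + 3 * ell.semi_axes[1])) / 2) * 2
    n_out = max(24, int(np.ceil(per_out / (0.9 * h_out))))
    outer_pts = ell.boundary_points(n_out)

    fixed_pts = np.vstack(loops_pts + [outer_pts])
    iface_tree = cKDTree(np.vstack(loops_pts))

    # interior lattice, thinned for grading
    pad = 2 * max(target_h, h_out)
    bbox = (outer_pts.min(axis=0) - pad, outer_pts.max(axis=0) + pad)
    lattice = _hex_lattice(bbox, target_h)
    rho = ell.normalized_radius(lattice)
    rmin = min(ell.semi_axes)
    inside = rho < 1.0 - 0.7 * h_out / rmin
    lattice = lattice[inside]
    d_iface, _ = iface_tree.query(lattice)
    if h_far is not None and h_far > target_h:
        rng = np.random.default_rng(0)
        h_loc = np.minimum(h_far, target_h + 0.35 * np.maximum(d_iface - 3 * target_h, 0.0))
        keep_p = (target_h / h_loc) ** 2
        lattice = lattice[rng.random(len(lattice)) < keep_p]
        d_iface, _ = iface_tree.query(lattice)
        h_loc = np.minimum(h_far, target_h + 0.35 * np.maximum(d_iface - 3 * target_h, 0.0))
        clear = d_iface > 0.7 * hb + 0.0 * h_loc
    else:
        clear = d_iface > 0.7 * hb
    lattice = lattice[clear]
    # keep clear of the outer boundary too
    d_out = cKDTree(outer_pts).query(lattice)[0]
    lattice = lattice[d_out > 0.6 * h_out]

    extra: list[np.ndarray] = []
    for _round in range(max_conformity_rounds):
        nodes = np.vstack([fixed_pts] + ([np.vstack(extra)] if extra else [])
                          + [lattice])
        n_fixed = len(fixed_pts) + (len(np.vstack(extra)) if extra else 0)
        tri = Delaunay(nodes)
        triangles = tri.simplices

        # drop triangles whose centroid lies outside the outer ellipse
        cent = nodes[triangles].mean(axis=1)
        keep = ell.normalized_radius(cent) < 1.0
        triangles = triangles[keep]

        # smoothing of free interior nodes (improves quality a lot)
        for _ in range(smooth_iters):
            e = np.sort(triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
            e = np.unique(e, axis=0)
            acc = np.zeros_like(nodes)
            cnt = np.zeros(len(nodes))
            np.add.at(acc, e[:, 0], nodes[e[:, 1]])
            np.add.at(acc, e[:, 1], nodes[e[:, 0]])
            np.add.at(cnt, e[:, 0], 1)
            np.add.at(cnt, e[:, 1], 1)
            free = np.arange(len(nodes)) >= n_fixed
            mov = free & (cnt > 0)
            nodes[mov] = acc[mov] / cnt[mov, None]
            tri = Delaunay(nodes)
            triangles = tri.simplices
            cent = nodes[triangles].mean(axis=1)
            triangles = triangles[ell.normalized_radius(cent) < 1.0]

        # conformity: every consecutive interface pair must be an edge
        edges = _edge_set(triangles)
        missing = []
        offset = 0
        for pts_loop in loops_pts:
            nb = len(pts_loop)
            for i in range(nb):
                a, b = offset + i, offset + (i + 1) % nb
                if (min(a, b), max(a, b)) not in edges:
                    missing.append(0.5 * (pts_loop[i] + pts_loop[(i + 1) % nb]))
            offset += nb
        if not missing:
            break
        extra.append(np.asarray(missing))
    else:
        raise GeometryError("could not enforce interface conformity; "
                            "geometry may be pathological at this mesh size")

    # drop degenerate hull slivers before compressing (they would leave
    # zero-mass rows in the FEM operators)
    pts_tri = nodes[triangles]
    v1 = pts_tri[:, 1] - pts_tri[:, 0]
    v2 = pts_tri[:, 2] - pts_tri[:, 0]
    areas = 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    e_all0 = np.sort(triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    e_uniq0, counts0 = np.unique(e_all0, axis=0, return_counts=True)
    hull_nodes = np.unique(e_uniq0[counts0 == 1])
    onhull = np.isin(triangles, hull_nodes).any(axis=1)
    degenerate = areas < 1e-10 * target_h ** 2
    _angles = _triangle_min_angles(nodes, triangles)
    drop = degenerate | (onhull & (_angles < min_angle_floor))
    if drop.any():
        triangles = triangles[~drop]

    # compress to nodes actually used by kept triangles (dropped slivers
    # can orphan nodes, which would produce singular FEM rows)
    used = np.unique(triangles)
    remap = -np.ones(len(nodes), dtype=int)
    remap[used] = np.arange(len(used))
    if len(used) < len(nodes):
        nodes = nodes[used]
        triangles = remap[triangles]
    else:
        remap = np.arange(len(nodes))

    # subdomain labels by centroid-in-epithelium
    cent = nodes[triangles].mean(axis=1)
    labels = np.full(len(triangles), MESENCHYME, dtype=int)
    for curve in domain.epithelia:
        inside = _MplPath(curve.points).contains_points(cent)
        labels[inside] = EPITHELIUM

    # interface loops reference the fixed boundary nodes (via the remap)
    interface_loops = []
    offset = 0
    stalk_mask_nodes = np.zeros(len(nodes), dtype=bool)
    for pts_loop, stalk_flags in zip(loops_pts, loops_stalk):
        nb = len(pts_loop)
        loop = remap[np.arange(offset, offset + nb)]
        if np.any(loop < 0):
            raise GeometryError("an interface node was orphaned during meshing")
        interface_loops.append(loop)
        stalk_mask_nodes[loop] = stalk_flags
        offset += nb

    # boundary edges: outer = edges with a single adjacent triangle
    e_all = np.sort(triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    e_uniq, counts = np.unique(e_all, axis=0, return_counts=True)
    outer_edges = e_uniq[counts == 1]

    iface_edges, stalk_edges = [], []
    for loop, stalk_flags in zip(interface_loops, loops_stalk):
        nb = len(loop)
        for i in range(nb):
            a, b = loop[i], loop[(i + 1) % nb]
            if stalk_flags[i] and stalk_flags[(i + 1) % nb]:
                stalk_edges.append((a, b))
            else:
                iface_edges.append((a, b))
    boundary_edges = {
        EDGE_OUTER: outer_edges,
        EDGE_INTERFACE: np.asarray(iface_edges, dtype=int).reshape(-1, 2),
        EDGE_STALK: np.asarray(stalk_edges, dtype=int).reshape(-1, 2),
    }

    mesh = Mesh(nodes=nodes, triangles=triangles, subdomain_labels=labels,
                interface_loops=interface_loops, boundary_edges=boundary_edges,
                target_h=target_h, stalk_node_mask=stalk_mask_nodes,
                interface_arcs=loops_arcs,
                curve_lengths=[c.total_length for c in domain.epithelia])
    qual = mesh.min_angles().min()
    if qual < min_angle_floor:
        raise GeometryError(
            f"mesh quality floor violated: min angle {qual:.2f} deg "
            f"< {min_angle_floor} deg at h={target_h}")
    return mesh
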