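"""Tip-density morphometrics on tip coordinate clouds (minimum-volume
enclosing ellipsoid, area per tip, neighbourhood median tip-to-tip
distance, volume binning) and Welch's t-test from group summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree
from scipy.stats import t as _student_t

from .errors import InputError

__all__ = [
    "TipCloud",
    "GroupSummary",
    "min_enclosing_ellipsoid",
    "area_per_tip",
    "median_t2t",
    "welch_t_from_summary",
    "se_from_summary",
    "bin_by_volume",
]


@dataclass
class TipCloud:
    """Tip coordinates (micrometres) of one sample."""

    tips: np.ndarray
    sample_id: str = ""
    genotype: str = ""

    def __post_init__(self):
        tips = np.asarray(self.tips, dtype=float)
        if tips.ndim != 2 or tips.shape[1] not in (2, 3):
            raise InputError("tips must be (N, 2) or (N, 3)")
        if not np.all(np.isfinite(tips)):
            raise InputError("tip coordinates must be finite")
        self.tips = tips

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def dim(self) -> int:
        return self.tips.shape[1]

    def to_csv(self, path):
        cols = ["x", "y", "z"][: self.dim]
        df = pd.DataFrame(self.tips, columns=cols)
        df.insert(0, "genotype", self.genotype)
        df.insert(0, "sample_id", self.sample_id)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> list["TipCloud"]:
        df = pd.read_csv(path)
        cols = [c for c in ("x", "y", "z") if c in df.columns]
        out = []
        for sid, grp in df.groupby("sample_id", sort=False):
            out.append(cls(tips=grp[cols].to_numpy(),
                           sample_id=str(sid),
                           genotype=str(grp["genotype"].iloc[0])))
        return out


@dataclass(frozen=True)
class GroupSummary:
    """Printed per-group statistics: tip count, mean and SD (micrometres)."""

    n: int
    mean: float
    sd: float
    median: float | None = None
    se: float | None = None

    def __post_init__(self):
        if self.n < 2:
            raise InputError("group needs n >= 2")
        if self.sd < 0:
            raise InputError("sd must be >= 0")


@dataclass
class Ellipsoid:
    center: np.ndarray
    semi_axes: np.ndarray  # descending
    axes_dirs: np.ndarray  # columns = directions

    @property
    def volume(self) -> float:
        if len(self.semi_axes) == 3:
            return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))
        return float(np.pi * np.prod(self.semi_axes))

    @property
    def surface_area(self) -> float:
        """Thomsen's symmetric approximation (exponent p = 1.6075) for
        3D; Ramanujan perimeter for 2D."""
        ax = self.semi_axes
        if len(ax) == 3:
            p = 1.6075
            a, b, c = ax
            s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
            return float(4.0 * np.pi * s ** (1.0 / p))
        a, b = ax
        h = ((a - b) / (a + b)) ** 2
        return float(np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h))))


def min_enclosing_ellipsoid(points: np.ndarray, tol: float = 1e-4,
                            max_iter: int = 20000) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid by Khachiyan's barycentric
    coordinate-ascent scheme."""
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] not in (2, 3):
        raise InputError("points must be (N, 2) or (N, 3)")
    N, d = P.shape
    if N < d + 1:
        raise InputError(f"need at least {d + 1} points in {d}D")
    if np.linalg.matrix_rank(P - P.mean(axis=0)) < d:
        raise InputError("degenerate (coplanar/collinear) points; "
                         "use the lower-dimensional mode")
    Q = np.column_stack([P, np.ones(N)]).T  # (d+1, N)
    u = np.full(N, 1.0 / N)
    err = tol + 1.0
    it = 0
    while err > tol and it < max_iter:
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(X, Q))
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1.0) * (M[j] - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        err = float(np.linalg.norm(new_u - u))
        u = new_u
        it += 1
    center = P.T @ u
    # ellipsoid (x-c)^T A (x-c) <= 1 with A = inv(P'UP - cc')/d
    A = np.linalg.inv(P.T @ np.diag(u) @ P - np.outer(center, center)) / d
    lam, vec = np.linalg.eigh(A)
    semi = 1.0 / np.sqrt(lam)  # ascending lam -> descending semi
    order = np.argsort(semi)[::-1]
    semi, vec = semi[order], vec[:, order]
    # inflate by the worst residual so every point is strictly enclosed
    # (the iterate is a slightly-too-small approximation at finite tol)
    dist = np.einsum("ij,jk,ik->i", P - center, A, P - center)
    semi = semi * np.sqrt(max(float(dist.max()), 1.0))
    return Ellipsoid(center=center, semi_axes=semi, axes_dirs=vec)


def area_per_tip(cloud: TipCloud, tol: float = 1e-4) -> float:
    """Surface area of the minimum enclosing ellipsoid divided by the
    number of tips (square micrometres per tip)."""
    ell = min_enclosing_ellipsoid(cloud.tips, tol=tol)
    return ell.surface_area / cloud.n_tips


def _delaunay_neighbours(tips: np.ndarray):
    tri = Delaunay(tips)
    n = len(tips)
    nb = [set() for _ in range(n)]
    for simplex in tri.simplices:
        for i in simplex:
            nb[i].update(simplex)
    for i in range(n):
        nb[i].discard(i)
    return [np.fromiter(s, dtype=int) for s in nb]


def median_t2t(cloud: TipCloud, neighbourhood: str = "delaunay",
               k: int = 6, cap_factor: float = 3.0):
    """Per-tip median distance to its immediate neighbourhood and the
    cloud-level median of those values.

    ``neighbourhood='delaunay'`` uses Delaunay natural neighbours with
    distances capped at ``cap_factor`` times the cloud's global median
    nearest-neighbour spacing; ``'knn'`` uses the ``k`` nearest tips.
    Returns (per_tip_medians, cloud_median).
    """
    tips = cloud.tips
    if len(tips) < 2:
        raise InputError("need at least two tips")
    if len(tips) == 2:
        d = float(np.linalg.norm(tips[0] - tips[1]))
        return np.array([d, d]), d
    tree = cKDTree(tips)
    nn_d, _ = tree.query(tips, k=2)
    global_med = float(np.median(nn_d[:, 1]))
    cap = cap_factor * global_med

    if neighbourhood == "delaunay":
        try:
            nbs = _delaunay_neighbours(tips)
        except Exception:
            neighbourhood = "knn"
    if neighbourhood == "knn":
        kk = min(k + 1, len(tips))
        _, idx = tree.query(tips, k=kk)
        nbs = [row[1:] for row in idx]

    per_tip = np.empty(len(tips))
    for i, nb in enumerate(nbs):
        d = np.linalg.norm(tips[nb] - tips[i], axis=1)
        d = d[d <= cap]
        if len(d) == 0:  # cap removed everything: fall back to nearest
            d = np.array([nn_d[i, 1]])
        per_tip[i] = np.median(d)
    return per_tip, float(np.median(per_tip))


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary):
    """Welch's unequal-variance t-test from summary statistics.

    Returns (t, df, two-sided p): t = (m1 - m2)/sqrt(s1^2/n1 + s2^2/n2),
    Welch-Satterthwaite degrees of freedom, p from the Student-t
    survival function.
    """
    v1 = g1.sd ** 2 / g1.n
    v2 = g2.sd ** 2 / g2.n
    if v1 + v2 == 0:
        if g1.mean == g2.mean:
            return 0.0, float(g1.n + g2.n - 2), 1.0
        return np.inf, float(g1.n + g2.n - 2), 0.0
    t = (g1.mean - g2.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    p = 2.0 * float(_student_t.sf(abs(t), df))
    return float(t), float(df), p


def se_from_summary(sd: float, n: int) -> float:
    """Standard error of the mean, sd / sqrt(n)."""
    if n < 1:
        raise InputError("n must be >= 1")
    if sd < 0:
        raise InputError("sd must be >= 0")
    return sd / np.sqrt(n)


def bin_by_volume(samples, bin_edges):
    """Assign (item, volume) pairs to half-open bins [lo, hi); items
    whose volume falls outside all bins are returned under
    'unassigned'."""
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise InputError("bin edges must be strictly increasing")
    bins = {i: [] for i in range(1, len(edges))}
    unassigned = []
    for item, vol in samples:
        if vol <= 0:
            raise InputError("volumes must be positive")
        idx = int(np.searchsorted(edges, vol, side="right"))
        if 1 <= idx < len(edges):
            bins[idx].append(item)
        else:
            unassigned.append(item)
    bins["unassigned"] = unassigned
    return bins
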