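"""Non-metric multidimensional scaling and standard ellipses.

The nMDS minimises Kruskal stress-1 by alternating isotonic regression of
the configuration distances on the dissimilarity ranks with a Guttman
(majorization) update of the configuration.  Standard ellipses are the
Mahalanobis radius-1 ellipses of a bivariate point cloud; for a bivariate
normal they enclose 1 - exp(-1/2) ~ 39.4 % of the mass, the conventional
"40 %" core niche.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .records import DistanceMatrix

__all__ = ["NMDSResult", "Ellipse", "nmds", "core_ellipse",
           "ellipse_overlap"]


@dataclass
class NMDSResult:
    coordinates: np.ndarray         # n x dims, centred, PCA-rotated
    stress: float                   # Kruskal stress-1
    stress_path: np.ndarray         # per-iteration stress of the best start
    n_restarts: int
    converged: bool
    seed: int


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(d @ d)
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _run_smacof(delta: np.ndarray, order: np.ndarray, x0: np.ndarray,
                max_iter: int, tol: float):
    """One nMDS start: returns (config, stress, stress path)."""
    n = x0.shape[0]
    iu = np.triu_indices(n, k=1)
    iso = IsotonicRegression()
    x = x0.copy()
    path = []
    prev = np.inf
    ranks = np.arange(order.size, dtype=float)
    ssq_delta = float(delta @ delta)
    for _ in range(max_iter):
        d = pdist(x)
        # keep the configuration on the dissimilarity scale (stress-1 is
        # scale-invariant, so without this the size drifts)
        ssq_d = float(d @ d)
        if ssq_d > 0:
            c = np.sqrt(ssq_delta / ssq_d)
            x *= c
            d *= c
        # monotone regression of distances on dissimilarity ranks
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(ranks, d[order])
        s = _stress1(d, dhat)
        path.append(s)
        if prev - s < tol:
            break
        prev = s
        # Guttman transform towards the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = np.zeros((n, n))
        B[iu] = -ratio
        B += B.T
        np.fill_diagonal(B, -B.sum(axis=1))
        x = (B @ x) / n
    return x, path[-1], np.asarray(path)


def nmds(dist: DistanceMatrix | np.ndarray, dims: int = 2,
         n_restarts: int = 20, seed: int = 0, max_iter: int = 500,
         tol: float = 1e-6) -> NMDSResult:
    """Kruskal non-metric MDS of a dissimilarity matrix.

    The first start is a classical (metric) MDS embedding, the remaining
    ``n_restarts - 1`` are random; the lowest-stress configuration wins and
    is centred and rotated to its principal axes so repeated runs are
    comparable.
    """
    dm = dist.values if isinstance(dist, DistanceMatrix) else \
        np.asarray(dist, dtype=float)
    n = dm.shape[0]
    if n < 4:
        raise ValueError("nMDS needs at least 4 objects")
    delta = squareform(dm, checks=False)
    if np.ptp(delta) == 0:
        import warnings
        warnings.warn("all dissimilarities equal; configuration is "
                      "arbitrary", RuntimeWarning)
    order = np.argsort(delta, kind="stable")

    # classical MDS start via double-centred eigendecomposition
    J = np.eye(n) - np.ones((n, n)) / n
    B0 = -0.5 * J @ (dm ** 2) @ J
    w, v = np.linalg.eigh(B0)
    idx = np.argsort(w)[::-1][:dims]
    x_cmds = v[:, idx] * np.sqrt(np.maximum(w[idx], 1e-12))

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(n_restarts, 1)):
        x0 = x_cmds if r == 0 else rng.normal(size=(n, dims)) * delta.mean()
        x, s, path = _run_smacof(delta, order, x0, max_iter, tol)
        if best is None or s < best[1]:
            best = (x, s, path)
    x, s, path = best
    x = x - x.mean(axis=0)
    # principal-axis rotation with a deterministic sign convention
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(x.shape[1]):   # fix reflection: largest |coord| positive
        col = x[:, j]
        if abs(col.min()) > col.max():
            x[:, j] = -col
    return NMDSResult(coordinates=x, stress=s, stress_path=path,
                      n_restarts=n_restarts,
                      converged=bool(path.size < max_iter), seed=seed)


@dataclass
class Ellipse:
    """Mahalanobis radius-1 (standard) ellipse of a bivariate cloud."""

    center: np.ndarray
    cov: np.ndarray
    semi_axes: tuple[float, float] = field(init=False)
    orientation: float = field(init=False)     # radians of major axis
    area: float = field(init=False)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        w, v = np.linalg.eigh(self.cov)
        if w[0] <= 0:
            raise ValueError("covariance is singular or not positive "
                             "definite")
        self.semi_axes = (float(np.sqrt(w[1])), float(np.sqrt(w[0])))
        self.orientation = float(np.arctan2(v[1, 1], v[0, 1]))
        self.area = float(np.pi * np.sqrt(np.linalg.det(self.cov)))

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the radius-1 ellipse."""
        diff = np.atleast_2d(pts) - self.center
        sol = np.linalg.solve(self.cov, diff.T).T
        return (diff * sol).sum(axis=1) <= 1.0

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        half = np.sqrt(np.diag(self.cov))
        return self.center - half, self.center + half


def core_ellipse(coords: np.ndarray, coverage: float = 0.40) -> Ellipse:
    """Standard ellipse of an n x 2 point set (n >= 3).

    ``coverage`` is nominal documentation only: the radius-1 ellipse of a
    bivariate normal holds ~39.35 % of the mass.  Area is
    pi * sqrt(det(S)) with the n-1 sample covariance S.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an n x 2 array with n >= 3")
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    return Ellipse(center=pts.mean(axis=0), cov=np.cov(pts.T, ddof=1))


def ellipse_overlap(e1: Ellipse, e2: Ellipse,
                    resolution: int = 1500) -> dict:
    """Intersection area of two standard ellipses by grid quadrature.

    The indicator of membership in both ellipses is integrated on a
    ``resolution`` x ``resolution`` grid over the intersection of their
    bounding boxes (default accurate to well under 0.5 % of the lens
    area).  Returns the shared area and the percentage of each ellipse it
    represents.
    """
    lo1, hi1 = e1.bounding_box()
    lo2, hi2 = e2.bounding_box()
    lo = np.maximum(lo1, lo2)
    hi = np.minimum(hi1, hi2)
    if np.any(hi <= lo):
        return {"area": 0.0, "pct_of_first": 0.0, "pct_of_second": 0.0}
    xs = np.linspace(lo[0], hi[0], resolution)
    ys = np.linspace(lo[1], hi[1], resolution)
    dx = (hi[0] - lo[0]) / (resolution - 1)
    dy = (hi[1] - lo[1]) / (resolution - 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = e1.contains(pts) & e2.contains(pts)
    area = float(inside.sum() * dx * dy)
    return {"area": area,
            "pct_of_first": 100.0 * area / e1.area,
            "pct_of_second": 100.0 * area / e2.area}
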