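"""DBH estimation: height slicing, 2D projection and robust circle fitting.

Each tree is sliced at three height intervals above local ground —
1.0–1.1 m, 1.1–1.2 m and 1.2–1.4 m — with a PassThrough filter (half-open
``[zmin, zmax)`` so the intervals tile 1.0–1.4 m without double counting).
The slice is projected to the horizontal plane and a circle is fitted with
RANSAC: three random points define a candidate circle, candidates outside the
radius limits are rejected, and the candidate with the most points within the
distance threshold wins.  The winner is refined by geometric least squares
(minimising radial residuals, the unbiased estimator under radial noise) and
its inlier set recomputed once.

Each fit reports a **credibility** ``C``: the ratio of inliers to the total
number of points in the slice, a [0, 1] score of how circle-like the slice is.
The circle diameter, in centimetres, is the DBH estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import least_squares

from .io_formats import PointCloud
from .tree_clustering import TreeInstance

__all__ = [
    "HeightInterval",
    "CircleModel",
    "DBHEstimate",
    "FitStatus",
    "CircleFitParams",
    "TooFewPointsError",
    "NoModelInRadiusLimitsError",
    "STANDARD_INTERVALS",
    "DEFAULT_INTERVAL",
    "passthrough",
    "project_xy",
    "fit_circle_ransac",
    "estimate_dbh",
]


@dataclass(frozen=True)
class HeightInterval:
    """Half-open slab of heights above ground, metres."""

    zmin: float
    zmax: float

    def __post_init__(self) -> None:
        if not self.zmin < self.zmax:
            raise ValueError("need zmin < zmax")

    @property
    def projection_plane_height(self) -> float:
        """The horizontal plane the slice is projected onto (the lower bound)."""
        return self.zmin

    @property
    def label(self) -> str:
        def fmt(v: float) -> str:
            s = f"{v:.2f}"
            return s[:-1] if s.endswith("0") else s
        return f"{fmt(self.zmin)}-{fmt(self.zmax)}m"


# the three standard slicing intervals; 1.0-1.1 m is the deployment default,
# being the interval with the smallest error on reference data
STANDARD_INTERVALS = (
    HeightInterval(1.0, 1.1),
    HeightInterval(1.1, 1.2),
    HeightInterval(1.2, 1.4),
)
DEFAULT_INTERVAL = STANDARD_INTERVALS[0]


class FitStatus(Enum):
    OK = "ok"
    TOO_FEW_POINTS = "too_few_points"
    NO_MODEL_IN_RADIUS_LIMITS = "no_model_in_radius_limits"


class TooFewPointsError(ValueError):
    """Fewer points than a circle hypothesis needs."""


class NoModelInRadiusLimitsError(RuntimeError):
    """No sampled circle hypothesis fell inside the radius limits."""


@dataclass
class CircleModel:
    """Fitted 2D circle with inlier bookkeeping and credibility C."""

    center_xy: tuple[float, float]
    radius: float
    inlier_indices: np.ndarray
    credibility: float
    n_points: int
    consensus_center_xy: tuple[float, float] | None = None
    consensus_radius: float | None = None
    consensus_inlier_indices: np.ndarray | None = None

    def residuals(self, points2d: np.ndarray) -> np.ndarray:
        """Signed radial residuals ||p - c|| - r."""
        d = np.linalg.norm(np.asarray(points2d) - np.asarray(self.center_xy), axis=1)
        return d - self.radius


@dataclass(frozen=True)
class CircleFitParams:
    """RANSAC circle-fit settings; radius limits cover DBH of 8-50 cm."""

    dist_threshold: float = 0.01
    radius_limits: tuple[float, float] = (0.04, 0.25)
    max_iterations: int = 500


@dataclass
class DBHEstimate:
    interval: HeightInterval
    status: FitStatus
    dbh_cm: float | None = None
    circle: CircleModel | None = None
    n_slice_points: int = 0


def passthrough(cloud: PointCloud, heights: np.ndarray, zmin: float,
                zmax: float) -> PointCloud:
    """Keep points whose height lies in the half-open band ``[zmin, zmax)``."""
    heights = np.asarray(heights)
    if heights.shape != (len(cloud),):
        raise ValueError("heights must align with the cloud")
    return cloud.select((heights >= zmin) & (heights < zmax))


def project_xy(cloud: PointCloud) -> np.ndarray:
    """Project onto the horizontal plane: drop z, keep (x, y) and order."""
    return cloud.coords[:, :2].copy()


def _circumcircles(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised circumscribed circles of point triples; flags collinear ones."""
    ax, ay = p0[:, 0], p0[:, 1]
    bx, by = p1[:, 0], p1[:, 1]
    cx, cy = p2[:, 0], p2[:, 1]
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ok = np.abs(d) > 1e-12
    dd = np.where(ok, d, 1.0)
    a2, b2, c2 = ax**2 + ay**2, bx**2 + by**2, cx**2 + cy**2
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / dd
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / dd
    centers = np.column_stack([ux, uy])
    radii = np.linalg.norm(centers - p0, axis=1)
    return centers, radii, ok


def _geometric_refine(points2d: np.ndarray, center: np.ndarray, radius: float
                      ) -> tuple[np.ndarray, float]:
    """Geometric least squares: minimise sum (||p-c|| - r)^2 from a warm start."""

    def resid(x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(points2d - x[:2], axis=1) - x[2]

    sol = least_squares(resid, x0=np.array([center[0], center[1], radius]),
                        method="lm", max_nfev=200)
    return sol.x[:2], float(sol.x[2])


def fit_circle_ransac(points2d: np.ndarray, dist_threshold: float = 0.01,
                      radius_limits: tuple[float, float] = (0.04, 0.25),
                      max_iterations: int = 500, seed: int = 0) -> CircleModel:
    """RANSAC circle fit with radius gating and geometric refinement.

    Raises
    ------
    TooFewPointsError
        Fewer than 3 points.
    NoModelInRadiusLimitsError
        No non-collinear sampled triple produced a radius inside the limits.
    """
    points2d = np.asarray(points2d, dtype=np.float64)
    n = len(points2d)
    if n < 3:
        raise TooFewPointsError(f"circle fit needs >= 3 points, got {n}")
    r_min, r_max = radius_limits
    if not (0 < r_min < r_max):
        raise ValueError("radius_limits must satisfy 0 < r_min < r_max")
    if dist_threshold <= 0:
        raise ValueError("dist_threshold must be positive")
    rng = np.random.default_rng(seed)

    triples = np.empty((max_iterations, 3), dtype=np.int64)
    for i in range(max_iterations):
        triples[i] = rng.choice(n, size=3, replace=False)
    centers, radii, ok = _circumcircles(points2d[triples[:, 0]],
                                        points2d[triples[:, 1]],
                                        points2d[triples[:, 2]])
    ok &= (radii >= r_min) & (radii <= r_max)
    if not ok.any():
        raise NoModelInRadiusLimitsError(
            f"no circle hypothesis with radius in [{r_min}, {r_max}] m"
        )
    valid_idx = np.flatnonzero(ok)
    best_count, best_hyp = -1, -1
    chunk = max(1, int(2e6 // max(n, 1)))
    for start in range(0, len(valid_idx), chunk):
        sel = valid_idx[start:start + chunk]
        d = np.linalg.norm(points2d[:, None, :] - centers[sel][None, :, :], axis=2)
        counts = (np.abs(d - radii[sel]) <= dist_threshold).sum(axis=0)
        j = int(np.argmax(counts))
        if counts[j] > best_count:  # first-found wins ties
            best_count, best_hyp = int(counts[j]), int(sel[j])

    c_center, c_radius = centers[best_hyp], float(radii[best_hyp])
    c_resid = np.abs(np.linalg.norm(points2d - c_center, axis=1) - c_radius)
    c_inliers = np.flatnonzero(c_resid <= dist_threshold)

    center, radius = _geometric_refine(points2d[c_inliers], c_center, c_radius)
    # a refinement that leaves the admissible radius band is discarded and the
    # consensus model kept
    if not (r_min <= radius <= r_max):
        center, radius = c_center, c_radius
    resid = np.abs(np.linalg.norm(points2d - center, axis=1) - radius)
    inliers = np.flatnonzero(resid <= dist_threshold)
    return CircleModel(
        center_xy=(float(center[0]), float(center[1])),
        radius=float(radius),
        inlier_indices=inliers,
        credibility=len(inliers) / n,
        n_points=n,
        consensus_center_xy=(float(c_center[0]), float(c_center[1])),
        consensus_radius=c_radius,
        consensus_inlier_indices=c_inliers,
    )


def estimate_dbh(tree: TreeInstance, cloud: PointCloud, heights: np.ndarray,
                 intervals: tuple[HeightInterval, ...] = STANDARD_INTERVALS,
                 fit_params: CircleFitParams | None = None,
                 min_points: int = 30, seed: int = 0
                 ) -> dict[HeightInterval, DBHEstimate]:
    """Estimate DBH of one tree at each height interval.

    For every interval: PassThrough slice of the tree's points (heights above
    local ground), projection to (x, y), RANSAC circle fit; DBH in cm is
    200 x radius.  Slices with fewer than ``min_points`` points, or with no
    admissible circle, yield a status instead of an exception.  Results are
    stored on ``tree.dbh_estimates`` and returned.
    """
    if not intervals:
        raise ValueError("need at least one height interval")
    if fit_params is None:
        fit_params = CircleFitParams()
    sub = cloud.select(tree.point_indices)
    sub_heights = np.asarray(heights)[tree.point_indices]
    results: dict[HeightInterval, DBHEstimate] = {}
    for k, interval in enumerate(intervals):
        slab = passthrough(sub, sub_heights, interval.zmin, interval.zmax)
        n_slice = len(slab)
        if n_slice < max(min_points, 3):
            results[interval] = DBHEstimate(interval, FitStatus.TOO_FEW_POINTS,
                                            n_slice_points=n_slice)
            continue
        pts2d = project_xy(slab)
        try:
            circle = fit_circle_ransac(
                pts2d,
                dist_threshold=fit_params.dist_threshold,
                radius_limits=fit_params.radius_limits,
                max_iterations=fit_params.max_iterations,
                seed=seed + k,
            )
        except NoModelInRadiusLimitsError:
            results[interval] = DBHEstimate(
                interval, FitStatus.NO_MODEL_IN_RADIUS_LIMITS, n_slice_points=n_slice
            )
            continue
        results[interval] = DBHEstimate(
            interval, FitStatus.OK, dbh_cm=200.0 * circle.radius,
            circle=circle, n_slice_points=n_slice,
        )
    tree.dbh_estimates = results
    return results
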