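"""Ground extraction and height normalisation.

The map is gravity-aligned (z up), so the ground is modelled as the single
dominant near-horizontal plane, found with classic RANSAC: repeatedly
hypothesise a plane from three random points, discard hypotheses tilted more
than ``max_tilt_deg`` from horizontal (walls and stems must not win the
consensus), and keep the hypothesis with the most points within
``dist_threshold``.  The winner is refined once by total least squares on its
inliers and the inlier set is recomputed.

Heights above ground come in two flavours: signed distance to the global
plane, or a grid DTM (per-cell minimum ground elevation, bilinearly
interpolated) that follows terrain undulation and therefore places breast
height correctly on sloping ground.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .io_formats import PointCloud

__all__ = ["PlaneModel", "fit_plane_ransac", "remove_ground", "height_above_ground"]

logger = logging.getLogger("stemfit")


@dataclass
class PlaneModel:
    """Plane ``normal . p + offset = 0`` with unit normal and ``normal_z > 0``."""

    normal: np.ndarray
    offset: float
    inlier_indices: np.ndarray
    iterations_used: int
    consensus_normal: np.ndarray | None = None
    consensus_offset: float | None = None
    consensus_inlier_indices: np.ndarray | None = None

    def distance(self, coords: np.ndarray) -> np.ndarray:
        """Unsigned point-plane distance, metres."""
        return np.abs(self.signed_distance(coords))

    def signed_distance(self, coords: np.ndarray) -> np.ndarray:
        """Signed distance along the (upward) normal."""
        return np.asarray(coords) @ self.normal + self.offset


def _canonical(normal: np.ndarray, offset: float) -> tuple[np.ndarray, float]:
    if normal[2] < 0:
        return -normal, -offset
    return normal, offset


def _tls_plane(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane: centroid + smallest-eigenvector normal."""
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    normal = vecs[:, 0]
    normal = normal / np.linalg.norm(normal)
    offset = -float(normal @ centroid)
    return _canonical(normal, offset)


def fit_plane_ransac(cloud: PointCloud, dist_threshold: float = 0.05,
                     max_iterations: int = 1000, max_tilt_deg: float = 15.0,
                     seed: int = 0) -> PlaneModel:
    """Fit the dominant near-horizontal plane with RANSAC + TLS refinement.

    Parameters
    ----------
    dist_threshold : float
        Inlier distance to the plane, metres.
    max_iterations : int
        Number of 3-point hypotheses drawn.
    max_tilt_deg : float
        Maximum angle between the plane normal and the z axis; steeper
        hypotheses are skipped so vertical structure cannot win.
    seed : int
        Makes the sampling, and hence the fit, deterministic.

    Raises
    ------
    ValueError
        Fewer than 3 points, or no hypothesis within the tilt gate (the error
        suggests increasing ``max_tilt_deg``).
    """
    coords = cloud.coords
    n = len(coords)
    if n < 3:
        raise ValueError(f"plane fit needs >= 3 points, got {n}")
    if dist_threshold <= 0:
        raise ValueError("dist_threshold must be positive")
    rng = np.random.default_rng(seed)

    # draw all minimal samples up front (vectorised distinct triples)
    triples = np.empty((max_iterations, 3), dtype=np.int64)
    for i in range(max_iterations):
        triples[i] = rng.choice(n, size=3, replace=False)
    p0, p1, p2 = (coords[triples[:, j]] for j in range(3))
    normals = np.cross(p1 - p0, p2 - p0)
    norms = np.linalg.norm(normals, axis=1)
    valid = norms > 1e-12  # collinear triples are skipped
    normals[valid] /= norms[valid, None]
    flip = normals[:, 2] < 0
    normals[flip] *= -1.0
    cos_tilt = np.cos(np.deg2rad(max_tilt_deg))
    valid &= normals[:, 2] >= cos_tilt
    if not valid.any():
        raise ValueError(
            "no RANSAC plane hypothesis satisfied the tilt constraint; "
            "increase max_tilt_deg or check that z is the up axis"
        )
    offsets = -np.einsum("ij,ij->i", normals, p0)

    # consensus counting, chunked over hypotheses; float32 on big clouds keeps
    # the distance matrix in cache (final inliers are recomputed in float64)
    use32 = n > 100_000
    pts = coords.astype(np.float32) if use32 else coords
    hyp_n = normals.astype(pts.dtype)
    hyp_o = offsets.astype(pts.dtype)
    thr = pts.dtype.type(dist_threshold)
    valid_idx = np.flatnonzero(valid)
    best_count, best_hyp = -1, -1
    chunk = max(1, int(2e7 // max(n, 1)))
    for start in range(0, len(valid_idx), chunk):
        sel = valid_idx[start:start + chunk]
        dist = np.abs(pts @ hyp_n[sel].T + hyp_o[sel])
        counts = (dist <= thr).sum(axis=0)
        j = int(np.argmax(counts))
        if counts[j] > best_count:  # ties broken by first-found
            best_count, best_hyp = int(counts[j]), int(sel[j])

    c_normal, c_offset = _canonical(normals[best_hyp], float(offsets[best_hyp]))
    c_inliers = np.flatnonzero(np.abs(coords @ c_normal + c_offset) <= dist_threshold)

    # one TLS refinement on the consensus inliers, then recompute inliers once
    normal, offset = _tls_plane(coords[c_inliers])
    inliers = np.flatnonzero(np.abs(coords @ normal + offset) <= dist_threshold)
    return PlaneModel(
        normal=normal,
        offset=offset,
        inlier_indices=inliers,
        iterations_used=max_iterations,
        consensus_normal=c_normal,
        consensus_offset=c_offset,
        consensus_inlier_indices=c_inliers,
    )


def remove_ground(cloud: PointCloud, plane: PlaneModel,
                  dist_threshold: float = 0.25) -> tuple[PointCloud, PointCloud]:
    """Split the cloud into (ground, nonground) around the fitted plane.

    Ground is every point within ``dist_threshold`` of the plane; the split is
    an exact partition.  The removal band is typically wider than the plane-fit
    threshold so undulating terrain is captured whole.
    """
    dist = plane.distance(cloud.coords)
    mask = dist <= dist_threshold
    ground = cloud.select(mask)
    nonground = cloud.select(~mask)
    logger.info("remove_ground: %d ground / %d nonground of %d points",
                len(ground), len(nonground), len(cloud))
    return ground, nonground


def height_above_ground(cloud: PointCloud, plane: PlaneModel,
                        mode: str = "plane", cell_size: float = 0.5,
                        ground: PointCloud | None = None) -> np.ndarray:
    """Per-point height above ground, metres.

    ``plane`` mode is the signed distance along the plane's upward normal.
    ``grid_dtm`` mode builds a digital terrain model from the ground cloud:
    the minimum z per ``cell_size`` grid cell (empty cells filled from the
    nearest occupied cell, logged), bilinearly interpolated at each point's
    (x, y); heights are z minus that terrain elevation.  The DTM mode keeps
    breast height at 1.3 m above *local* ground on undulating terrain.
    """
    if mode == "plane":
        return plane.signed_distance(cloud.coords)
    if mode != "grid_dtm":
        raise ValueError(f"mode must be 'plane' or 'grid_dtm', got {mode!r}")
    if ground is None or len(ground) == 0:
        raise ValueError("grid_dtm mode requires the ground cloud")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")

    gxy = ground.coords[:, :2]
    gz = ground.coords[:, 2]
    x0, y0 = gxy.min(axis=0)
    x1, y1 = gxy.max(axis=0)
    nx = max(2, int(np.ceil((x1 - x0) / cell_size)))
    ny = max(2, int(np.ceil((y1 - y0) / cell_size)))
    ix = np.clip(((gxy[:, 0] - x0) / cell_size).astype(np.int64), 0, nx - 1)
    iy = np.clip(((gxy[:, 1] - y0) / cell_size).astype(np.int64), 0, ny - 1)
    flat = ix * ny + iy
    dtm = np.full(nx * ny, np.inf)
    np.minimum.at(dtm, flat, gz)
    dtm[np.isinf(dtm)] = np.nan
    dtm = dtm.reshape(nx, ny)

    empty = np.isnan(dtm)
    if empty.any():
        logger.info("grid_dtm: filling %d empty cells from nearest occupied cell",
                    int(empty.sum()))
        occ = np.argwhere(~empty)
        if len(occ) == 0:
            raise ValueError("grid_dtm: no occupied cells")
        tree = cKDTree(occ.astype(float))
        holes = np.argwhere(empty)
        _, nearest = tree.query(holes.astype(float))
        dtm[holes[:, 0], holes[:, 1]] = dtm[occ[nearest, 0], occ[nearest, 1]]

    xc = x0 + (np.arange(nx) + 0.5) * cell_size
    yc = y0 + (np.arange(ny) + 0.5) * cell_size
    interp = RegularGridInterpolator((xc, yc), dtm, method="linear",
                                     bounds_error=False, fill_value=None)
    elev = interp(np.clip(cloud.coords[:, :2], [xc[0], yc[0]], [xc[-1], yc[-1]]))
    heights = cloud.coords[:, 2] - elev
    if not np.all(np.isfinite(heights)):
        raise RuntimeError("grid_dtm produced non-finite heights")
    return heights
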