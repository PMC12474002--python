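"""Scene cleanup ahead of registration: reorientation, grass and background removal.

Outdoor orchard captures share a layout: the tree fills the foreground, a
grass band covers the scene bottom and clutter sits far behind the tree.
The grass-removal heuristic exploits that layout.  A cloud whose depth
extent is at most ``thickness_limit`` (a single tree is only ~1.5 m thick)
is passed through untouched.  Otherwise iterative RANSAC plane segmentation
is run on the bottom band of the cloud; near-horizontal planes are
candidate grass, the most populated one is taken as the grass surface, and
every bottom-band point within ``plane_dist_max`` of it is removed.  When
no acceptable plane exists, a depth heuristic removes bottom-band points
lying behind the deepest upper-region point.

All functions operate in an upright frame: Y up, Z the (positive) depth
direction away from the sensor.  ``reorient`` maps raw camera-frame clouds
(Y down) into this frame, e.g. with a 180 deg rotation about Z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PreprocessConfig",
    "Plane",
    "reorient",
    "depth_thickness",
    "plane_angle",
    "point_plane_distance",
    "plane_distances",
    "segment_planes",
    "remove_grass",
    "cull_background",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Thresholds of the cleanup heuristics (all distances in meters).

    thickness_limit:
        depth extent above which a cloud is suspected to contain grass or
        background; a lone tree occupies about 1.5 m.
    grass_band / extended_band:
        heights above the cloud's lowest point delimiting the candidate
        grass band (0.4 m measured grass plus margin for camera tilt) and
        the slightly taller band used when harvesting points around the
        dominant plane.
    plane_dist_max:
        points of the extended band within this distance of the dominant
        grass plane are removed.
    angle_max_deg:
        maximum tilt (from vertical axis) for a plane to count as grass.
    min_inliers / ransac_dist / ransac_iters:
        plane-segmentation controls.
    background_cull:
        depth beyond the cloud's nearest point past which points are cut.
    """

    thickness_limit: float = 1.5
    grass_band: float = 0.6
    extended_band: float = 0.7
    plane_dist_max: float = 0.35
    angle_max_deg: float = 35.0
    min_inliers: int = 30
    ransac_dist: float = 0.02
    ransac_iters: int = 1000
    background_cull: float = 1.5

    def __post_init__(self) -> None:
        for name in ("thickness_limit", "grass_band", "extended_band", "plane_dist_max", "ransac_dist", "background_cull"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.extended_band < self.grass_band:
            raise ValueError("extended_band must be >= grass_band")
        if not 0.0 < self.angle_max_deg < 90.0:
            raise ValueError("angle_max_deg must lie in (0, 90)")
        if self.min_inliers < 3 or self.ransac_iters < 1:
            raise ValueError("min_inliers >= 3 and ransac_iters >= 1 required")


@dataclass(frozen=True)
class Plane:
    """Implicit plane a*x + b*y + c*z + d = 0 with (a, b, c) a unit normal."""

    a: float
    b: float
    c: float
    d: float
    n_inliers: int = 0

    def __post_init__(self) -> None:
        if abs(self.a**2 + self.b**2 + self.c**2 - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")
        if self.n_inliers < 0:
            raise ValueError("n_inliers must be >= 0")

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


def _points_of(P) -> np.ndarray:
    return P.points if hasattr(P, "points") else np.asarray(P, dtype=float).reshape(-1, 3)


def reorient(P, rot_z_deg: float, rot_y_deg: float):
    """Rotate about the origin by R_y(rot_y) @ R_z(rot_z) to stand the tree upright."""
    pts = _points_of(P)
    if len(pts) == 0:
        raise ValueError("cannot reorient an empty cloud")
    cz, sz = np.cos(np.deg2rad(rot_z_deg)), np.sin(np.deg2rad(rot_z_deg))
    cy, sy = np.cos(np.deg2rad(rot_y_deg)), np.sin(np.deg2rad(rot_y_deg))
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    Ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    rotated = pts @ (Ry @ Rz).T
    if hasattr(P, "with_points"):
        return P.with_points(rotated)
    return rotated


def depth_thickness(P) -> float:
    """Extent of the cloud along the depth (Z) axis."""
    pts = _points_of(P)
    if len(pts) == 0:
        raise ValueError("empty cloud has no thickness")
    return float(pts[:, 2].max() - pts[:, 2].min())


def plane_angle(plane: Plane) -> float:
    """Tilt of the plane's normal from the vertical axis, in degrees.

    The absolute value of the Y component is used so that upward- and
    downward-pointing normals (RANSAC's sign is arbitrary) score equally.
    """
    ny = abs(plane.b)
    return float(np.degrees(np.arccos(np.clip(ny, -1.0, 1.0))))


def point_plane_distance(p, plane) -> float:
    """Orthogonal distance |ax + by + cz + d| / sqrt(a^2 + b^2 + c^2).

    ``plane`` may be a :class:`Plane` or a raw (a, b, c, d) coefficient
    quadruple; the formula is homogeneous, so any nonzero scaling of the
    coefficients gives the same distance.
    """
    p = np.asarray(p, dtype=float)
    a, b, c, d = (plane.a, plane.b, plane.c, plane.d) if isinstance(plane, Plane) else plane
    norm = np.sqrt(a * a + b * b + c * c)
    if norm < 1e-300:
        raise ValueError("plane normal must be nonzero")
    return float(abs(a * p[0] + b * p[1] + c * p[2] + d) / norm)


def plane_distances(points: np.ndarray, plane: Plane) -> np.ndarray:
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    norm = np.sqrt(plane.a**2 + plane.b**2 + plane.c**2)
    return np.abs(points @ plane.normal + plane.d) / norm


def _fit_plane_ransac(pts: np.ndarray, dist: float, iters: int, rng) -> tuple[Plane, np.ndarray] | None:
    """Best plane by inlier count over 3-point hypotheses, PCA-refit on inliers."""
    n = len(pts)
    if n < 3:
        return None
    best_count = -1
    best_normal = None
    best_d = 0.0
    chunk = 256
    for start in range(0, iters, chunk):
        m = min(chunk, iters - start)
        tri = rng.integers(0, n, size=(m, 3))
        p0, p1, p2 = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
        normals = np.cross(p1 - p0, p2 - p0)
        norms = np.linalg.norm(normals, axis=1)
        ok = norms > 1e-12
        if not ok.any():
            continue
        normals = normals[ok] / norms[ok, None]
        d = -np.einsum("ij,ij->i", normals, p0[ok])
        dists = np.abs(pts @ normals.T + d)  # (n, m_ok)
        counts = (dists <= dist).sum(axis=0)
        i = int(np.argmax(counts))
        if counts[i] > best_count:
            best_count = int(counts[i])
            best_normal = normals[i]
            best_d = float(d[i])
    if best_normal is None:
        return None
    inliers = np.abs(pts @ best_normal + best_d) <= dist
    sub = pts[inliers]
    if len(sub) >= 3:  # least-squares refit on the consensus set
        centroid = sub.mean(axis=0)
        _, _, vt = np.linalg.svd(sub - centroid, full_matrices=False)
        normal = vt[-1]
        d = float(-normal @ centroid)
        inliers = np.abs(pts @ normal + d) <= dist
    else:
        normal, d = best_normal, best_d
    plane = Plane(float(normal[0]), float(normal[1]), float(normal[2]), float(d), int(inliers.sum()))
    return plane, inliers


def segment_planes(B, cfg: PreprocessConfig, seed: int = 0) -> list[Plane]:
    """Iteratively peel RANSAC planes off ``B``; keep the near-horizontal ones.

    Each round fits the best plane of the remaining points, stops when it
    supports fewer than ``min_inliers`` points, keeps it only when its tilt
    is within ``angle_max_deg``, and removes its inliers (kept or not)
    before the next round.  Runs while at least ``min_inliers`` points
    remain; kept planes are returned in detection order.
    """
    pts = _points_of(B).copy()
    rng = np.random.default_rng(seed)
    kept: list[Plane] = []
    while len(pts) >= cfg.min_inliers:
        fit = _fit_plane_ransac(pts, cfg.ransac_dist, cfg.ransac_iters, rng)
        if fit is None:
            break
        plane, inliers = fit
        if plane.n_inliers < cfg.min_inliers:
            break
        if plane_angle(plane) <= cfg.angle_max_deg:
            kept.append(plane)
        pts = pts[~inliers]
    return kept


def remove_grass(P, cfg: PreprocessConfig | None = None, seed: int = 0):
    """Remove the grass band (and low background) from an upright cloud.

    Returns a subset of ``P`` (same container type).  Clouds no thicker
    than ``thickness_limit`` along Z are returned unchanged.  Points at or
    above the extended band are never touched.
    """
    cfg = cfg or PreprocessConfig()
    pts = _points_of(P)
    if len(pts) == 0:
        raise ValueError("cannot remove grass from an empty cloud")
    has_select = hasattr(P, "select")

    def subset(mask):
        return P.select(mask) if has_select else pts[mask]

    if depth_thickness(pts) <= cfg.thickness_limit:
        return subset(np.ones(len(pts), dtype=bool))

    y_min = pts[:, 1].min()
    band = pts[:, 1] < y_min + cfg.grass_band
    planes = segment_planes(pts[band], cfg, seed=seed)
    if planes:
        counts = [pl.n_inliers for pl in planes]
        main = planes[int(np.argmax(counts))]  # argmax keeps the first on ties
        extended = pts[:, 1] < y_min + cfg.extended_band
        near = plane_distances(pts, main) <= cfg.plane_dist_max
        grass = extended & near
        return subset(~grass)
    upper = pts[:, 1] > y_min + cfg.grass_band
    if not upper.any():
        return subset(np.ones(len(pts), dtype=bool))
    z_max_upper = pts[upper, 2].max()  # deepest point of the upper region
    grass = band & (pts[:, 2] > z_max_upper)
    return subset(~grass)


def cull_background(P, cfg: PreprocessConfig | None = None):
    """Drop points more than ``background_cull`` behind the cloud's nearest point."""
    cfg = cfg or PreprocessConfig()
    pts = _points_of(P)
    if len(pts) == 0:
        raise ValueError("cannot cull an empty cloud")
    keep = pts[:, 2] <= pts[:, 2].min() + cfg.background_cull
    return P.select(keep) if hasattr(P, "select") else pts[keep]
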