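"""Robust multi-view rigid registration.

The pipeline aligns four partially overlapping views of a tree: both clouds
are voxel-downsampled (default 0.02 m), 33-bin FPFH descriptors are
computed, each source descriptor is matched to its nearest target
descriptor, and a rigid transform is estimated from the correspondences
under a truncated-least-squares (TLS) objective — residuals larger than
``noise_bound`` contribute a constant cost, so grossly wrong matches
(routinely the majority on sparse, self-similar branch structures) cannot
bias the estimate.  The TLS problem is solved by graduated non-convexity
(GNC): a convex surrogate is annealed toward the true objective while
rotation and translation are re-estimated by weighted Kabsch at each sweep.
The recovered transform is applied to the full-resolution source and the
views are accumulated sequentially in the first view's frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud, concat_clouds

__all__ = [
    "RigidTransform",
    "RobustSolverConfig",
    "FeatureSet",
    "CorrespondenceSet",
    "voxel_downsample",
    "voxel_groups",
    "estimate_normals",
    "fpfh_features",
    "match_features",
    "kabsch",
    "estimate_transform_robust",
    "apply_transform",
    "register_pair",
    "sequential_register",
]


@dataclass(frozen=True)
class RigidTransform:
    """p -> R @ p + t with R a proper rotation."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9 or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("R must be a proper rotation matrix")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(p) = self(other(p))."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.R
        M[:3, 3] = self.t
        return M

    @staticmethod
    def from_matrix(M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float).reshape(4, 4)
        return RigidTransform(M[:3, :3], M[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Geodesic magnitude of the rotation."""
        c = (np.trace(self.R) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_geodesic_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Geodesic distance between two rotations, in degrees."""
    c = (np.trace(np.asarray(R1).T @ np.asarray(R2)) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class RobustSolverConfig:
    """Truncated-least-squares solver settings.

    ``noise_bound`` (m) is the residual beyond which a correspondence is an
    outlier; by convention it matches the downsampling voxel size.
    ``gnc_factor`` is the annealing rate of the graduated non-convexity
    schedule, ``max_iterations`` bounds the sweeps, ``cost_threshold`` is
    the convergence tolerance on the weighted cost, and ``cbar`` scales the
    inlier threshold (kept at 1).  Scale estimation is fixed at 1 when
    ``estimate_scaling`` is false (clouds from a calibrated sensor share
    metric scale).
    """

    noise_bound: float = 0.02
    estimate_scaling: bool = False
    gnc_factor: float = 1.4
    max_iterations: int = 100
    cost_threshold: float = 1e-12
    cbar: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_bound <= 0:
            raise ValueError("noise_bound must be > 0")
        if self.gnc_factor <= 1:
            raise ValueError("gnc_factor must be > 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.estimate_scaling:
            raise NotImplementedError("scale estimation is not supported; scale is fixed at 1")


@dataclass(frozen=True)
class FeatureSet:
    """Per-point FPFH descriptors with the indices of their owner points."""

    descriptors: np.ndarray  # (N, 33), all entries >= 0
    indices: np.ndarray  # (N,) into the source cloud

    def __post_init__(self) -> None:
        d = np.asarray(self.descriptors, dtype=float)
        if d.ndim != 2 or d.shape[1] != 33:
            raise ValueError("descriptors must be (N, 33)")
        if (d < 0).any():
            raise ValueError("descriptors must be non-negative")
        object.__setattr__(self, "descriptors", d)
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.int64).ravel())
        if len(self.indices) != len(d):
            raise ValueError("indices length must match descriptor rows")

    def __len__(self) -> int:
        return len(self.descriptors)


@dataclass(frozen=True)
class CorrespondenceSet:
    """(source index, target index) pairs, at most one per source point."""

    pairs: np.ndarray  # (M, 2) int

    def __post_init__(self) -> None:
        p = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "pairs", p)
        if len(np.unique(p[:, 0])) != len(p):
            raise ValueError("at most one pair per source index")

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# voxel downsampling


def voxel_groups(points: np.ndarray, voxel: float) -> tuple[np.ndarray, np.ndarray]:
    """Group points into occupied voxels.

    Returns ``(inverse, n_voxels)``: for each point the id of its voxel, with
    ids ordered by first occurrence (deterministic for a fixed point order).
    """
    if voxel <= 0:
        raise ValueError("voxel size must be > 0")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    keys = np.floor(points / voxel).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    # reorder voxel ids by first occurrence so output order is stable
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return rank[inverse], len(order)


def voxel_downsample(P, voxel: float):
    """One point per occupied voxel, at the centroid of its members."""
    pts = P.points if hasattr(P, "points") else np.asarray(P, dtype=float).reshape(-1, 3)
    inverse, n_vox = voxel_groups(pts, voxel)
    counts = np.bincount(inverse, minlength=n_vox).astype(float)
    centroids = np.zeros((n_vox, 3))
    for k in range(3):
        centroids[:, k] = np.bincount(inverse, weights=pts[:, k], minlength=n_vox) / counts
    if hasattr(P, "points"):
        return PointCloud(points=centroids)
    return centroids


# ---------------------------------------------------------------------------
# FPFH


def estimate_normals(points: np.ndarray, radius: float) -> np.ndarray:
    """PCA normals from radius neighborhoods, oriented away from the centroid.

    Centroid-outward orientation is equivariant under rigid motion, which
    keeps the FPFH descriptors pose-invariant.  Points with fewer than three
    neighbors get an arbitrary unit normal.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    # accumulate neighborhood first/second moments (self included) per point
    count = np.ones(n)
    sums = points.copy()
    moments = points[:, :, None] * points[:, None, :]
    if len(pairs):
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        tgt = np.concatenate([pairs[:, 1], pairs[:, 0]])
        count += np.bincount(src, minlength=n)
        np.add.at(sums, src, points[tgt])
        np.add.at(moments, src, points[tgt][:, :, None] * points[tgt][:, None, :])
    mean = sums / count[:, None]
    cov = moments / count[:, None, None] - mean[:, :, None] * mean[:, None, :]
    normals = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    enough = count >= 3
    if enough.any():
        _, vecs = np.linalg.eigh(cov[enough])
        normals[enough] = vecs[:, :, 0]  # smallest-eigenvalue direction
    centroid = points.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, points - centroid) < 0
    normals[flip] *= -1.0
    return normals


def _pair_features(p_s, p_t, n_s, n_t):
    """Darboux-frame angle triplet (f1, f2, f3) for directed point pairs."""
    dp = p_t - p_s
    d = np.linalg.norm(dp, axis=1)
    valid = d > 1e-12
    e = np.zeros_like(dp)
    e[valid] = dp[valid] / d[valid, None]
    v = np.cross(e, n_s)
    vn = np.linalg.norm(v, axis=1)
    valid &= vn > 1e-9  # skip pairs whose direction is parallel to the normal
    v[valid] = v[valid] / vn[valid, None]
    w = np.cross(n_s, v)
    f1 = np.einsum("ij,ij->i", v, n_t)
    f2 = np.einsum("ij,ij->i", n_s, e)
    f3 = np.arctan2(np.einsum("ij,ij->i", w, n_t), np.einsum("ij,ij->i", n_s, n_t))
    return f1, f2, f3, d, valid


def _bin11(values, lo, hi):
    return np.clip(((values - lo) / (hi - lo) * 11.0).astype(np.int64), 0, 10)


def fpfh_features(P, normal_radius: float = 0.04, feature_radius: float = 0.10) -> FeatureSet:
    """33-bin Fast Point Feature Histograms for every point of ``P``.

    Simplified histograms (SPFH) over the three Darboux angles (11 bins
    each) are accumulated per point from its radius neighborhood and then
    re-weighted by inverse neighbor distance; each 11-bin block of the
    result is normalized to sum to 100.  A point with no neighbors inside
    ``feature_radius`` keeps an all-zero descriptor.  Deterministic for a
    fixed input.
    """
    pts = P.points if hasattr(P, "points") else np.asarray(P, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n < 5:
        raise ValueError("need at least 5 points for FPFH")
    normals = estimate_normals(pts, normal_radius)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(feature_radius, output_type="ndarray")
    spfh = np.zeros((n, 33))
    if len(pairs):
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])  # both directions
        tgt = np.concatenate([pairs[:, 1], pairs[:, 0]])
        f1, f2, f3, d, valid = _pair_features(pts[src], pts[tgt], normals[src], normals[tgt])
        src, tgt, d = src[valid], tgt[valid], d[valid]
        b1 = _bin11(f1[valid], -1.0, 1.0)
        b2 = _bin11(f2[valid], -1.0, 1.0)
        b3 = _bin11(f3[valid], -np.pi, np.pi)
        np.add.at(spfh, (src, b1), 1.0)
        np.add.at(spfh, (src, 11 + b2), 1.0)
        np.add.at(spfh, (src, 22 + b3), 1.0)
        # FPFH: own SPFH plus distance-weighted mean of neighbors' SPFHs
        k = np.bincount(src, minlength=n).astype(float)
        weighted = np.zeros_like(spfh)
        weights = 1.0 / np.maximum(d, 1e-9)
        chunk = 200_000  # bound the (pairs, 33) gather temporaries
        for s in range(0, len(src), chunk):
            sl = slice(s, s + chunk)
            np.add.at(weighted, src[sl], spfh[tgt[sl]] * weights[sl, None])
        has = k > 0
        fpfh = spfh.copy()
        fpfh[has] += weighted[has] / k[has, None]
    else:
        fpfh = spfh
    for block in (slice(0, 11), slice(11, 22), slice(22, 33)):
        s = fpfh[:, block].sum(axis=1)
        nz = s > 0
        fpfh[nz, block] = fpfh[nz, block] / s[nz, None] * 100.0
    return FeatureSet(descriptors=fpfh, indices=np.arange(n))


def _nearest_rows(A: np.ndarray, B: np.ndarray, block: int = 1024) -> np.ndarray:
    """Index of the Euclidean-nearest row of B for every row of A (blocked matmul).

    Distances are expanded as ||b||^2 - 2 a.b in float32; FPFH histograms are
    O(100)-scale so single precision leaves argmin ties essentially untouched.
    """
    A = np.ascontiguousarray(A, dtype=np.float32)
    B = np.ascontiguousarray(B, dtype=np.float32)
    b2 = np.einsum("ij,ij->i", B, B)
    out = np.empty(len(A), dtype=np.int64)
    for start in range(0, len(A), block):
        a = A[start : start + block]
        d2 = b2[None, :] - 2.0 * (a @ B.T)  # ||a||^2 omitted: constant per row
        out[start : start + block] = np.argmin(d2, axis=1)
    return out


def match_features(fs: FeatureSet, ft: FeatureSet) -> CorrespondenceSet:
    """Nearest target descriptor for every source descriptor (one-directional)."""
    if len(fs) == 0 or len(ft) == 0:
        raise ValueError("feature sets must be nonempty")
    nn = _nearest_rows(fs.descriptors, ft.descriptors)
    return CorrespondenceSet(pairs=np.column_stack([fs.indices, ft.indices[nn]]))


# ---------------------------------------------------------------------------
# rigid estimation


def _corr_points(corr: CorrespondenceSet, source, target):
    sp = source.points if hasattr(source, "points") else np.asarray(source, dtype=float).reshape(-1, 3)
    tp = target.points if hasattr(target, "points") else np.asarray(target, dtype=float).reshape(-1, 3)
    return sp[corr.pairs[:, 0]], tp[corr.pairs[:, 1]]


def _weighted_kabsch(P: np.ndarray, Q: np.ndarray, w: np.ndarray) -> RigidTransform:
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    pbar = (w[:, None] * P).sum(axis=0) / wsum
    qbar = (w[:, None] * Q).sum(axis=0) / wsum
    H = (w[:, None] * (P - pbar)).T @ (Q - qbar)
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-12 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) correspondence configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, qbar - R @ pbar)


def kabsch(corr: CorrespondenceSet, source, target) -> RigidTransform:
    """Closed-form least-squares rigid transform over the correspondences."""
    if len(corr) < 3:
        raise ValueError("need at least 3 correspondence pairs")
    P, Q = _corr_points(corr, source, target)
    return _weighted_kabsch(P, Q, np.ones(len(P)))


def estimate_transform_robust(
    corr: CorrespondenceSet, source, target, cfg: RobustSolverConfig | None = None
) -> RigidTransform:
    """Truncated-least-squares rigid estimation via graduated non-convexity.

    When every residual of the plain least-squares fit is already within the
    noise bound, the TLS and LS optima coincide and the Kabsch solution is
    returned directly.  Otherwise the GNC-TLS schedule is run: per-pair
    weights follow the closed-form update of the surrogate objective, the
    transform is re-fit by weighted Kabsch, and the convexity parameter mu
    is annealed by ``gnc_factor`` until the weighted cost converges or
    ``max_iterations`` sweeps elapse; a final plain Kabsch over the inlier
    set polishes the estimate.  Always returns a valid rigid transform,
    even when all pairs are outliers (no accuracy guarantee then).
    """
    cfg = cfg or RobustSolverConfig()
    if len(corr) < 3:
        raise ValueError("need at least 3 correspondence pairs")
    P, Q = _corr_points(corr, source, target)
    c2 = (cfg.cbar * cfg.noise_bound) ** 2

    T = _weighted_kabsch(P, Q, np.ones(len(P)))
    r2 = np.einsum("ij,ij->i", Q - T.apply(P), Q - T.apply(P))
    if r2.max() <= c2:
        return T

    mu = c2 / max(2.0 * r2.max() - c2, 1e-12)
    prev_cost = np.inf
    for _ in range(cfg.max_iterations):
        th_hi = (mu + 1.0) / mu * c2
        th_lo = mu / (mu + 1.0) * c2
        w = np.ones(len(P))
        w[r2 >= th_hi] = 0.0
        mid = (r2 > th_lo) & (r2 < th_hi)
        w[mid] = np.sqrt(c2 * mu * (mu + 1.0) / r2[mid]) - mu
        np.clip(w, 0.0, 1.0, out=w)
        if (w > 0).sum() < 3:
            break
        try:
            T = _weighted_kabsch(P, Q, w)
        except ValueError:
            break
        r2 = np.einsum("ij,ij->i", Q - T.apply(P), Q - T.apply(P))
        cost = float((w * r2).sum())
        if abs(prev_cost - cost) < cfg.cost_threshold and mu > 64.0:
            break
        prev_cost = cost
        mu *= cfg.gnc_factor

    inliers = r2 <= c2
    if inliers.sum() >= 3:
        try:
            T = _weighted_kabsch(P[inliers], Q[inliers], np.ones(int(inliers.sum())))
        except ValueError:
            pass
    return T


def apply_transform(P, T: RigidTransform):
    """Move every point by p -> R p + t; labels/colors/attributes follow unchanged."""
    if hasattr(P, "with_points"):
        return P.with_points(T.apply(P.points))
    return T.apply(P)


def register_pair(
    source,
    target,
    cfg: RobustSolverConfig | None = None,
    voxel: float = 0.02,
    normal_radius: float | None = None,
    feature_radius: float | None = None,
) -> tuple[RigidTransform, dict]:
    """One downsample / FPFH / match / robust-estimate step, source onto target.

    Returns the transform together with diagnostics (correspondence count,
    inlier count and mean inlier residual); success judgment is left to the
    caller.
    """
    cfg = cfg or RobustSolverConfig()
    normal_radius = 2.0 * voxel if normal_radius is None else normal_radius
    feature_radius = 5.0 * voxel if feature_radius is None else feature_radius
    src_pts = source.points if hasattr(source, "points") else np.asarray(source, dtype=float).reshape(-1, 3)
    tgt_pts = target.points if hasattr(target, "points") else np.asarray(target, dtype=float).reshape(-1, 3)
    src_down = voxel_downsample(src_pts, voxel)
    tgt_down = voxel_downsample(tgt_pts, voxel)
    fs = fpfh_features(src_down, normal_radius, feature_radius)
    ft = fpfh_features(tgt_down, normal_radius, feature_radius)
    corr = match_features(fs, ft)
    T = estimate_transform_robust(corr, src_down, tgt_down, cfg)
    res = np.linalg.norm(tgt_down[corr.pairs[:, 1]] - T.apply(src_down[corr.pairs[:, 0]]), axis=1)
    inl = res <= cfg.cbar * cfg.noise_bound
    diagnostics = {
        "n_correspondences": int(len(corr)),
        "n_inliers": int(inl.sum()),
        "mean_inlier_residual": float(res[inl].mean()) if inl.any() else float("nan"),
    }
    return T, diagnostics


def sequential_register(
    views: list,
    cfg: RobustSolverConfig | None = None,
    voxel: float = 0.02,
) -> tuple[PointCloud, list[RigidTransform]]:
    """Accumulate four views in the first view's frame.

    View 0 is the fixed target.  For each further view the transform is
    estimated on voxel-downsampled clouds and applied to the
    full-resolution view, which is then appended to the target.  Returns
    the merged cloud (point count = sum of the inputs; no deduplication)
    and the three estimated transforms.
    """
    if len(views) != 4:
        raise ValueError("sequential registration expects exactly 4 views")
    if any(len(v.points if hasattr(v, "points") else v) == 0 for v in views):
        raise ValueError("all views must be nonempty")
    cfg = cfg or RobustSolverConfig()

    def as_cloud(v) -> PointCloud:
        if isinstance(v, PointCloud):
            return v
        if hasattr(v, "to_cloud"):
            return v.to_cloud()
        return PointCloud(points=np.asarray(v, dtype=float))

    target = as_cloud(views[0])
    transforms: list[RigidTransform] = []
    for k in range(1, 4):
        source = as_cloud(views[k])
        T, _ = register_pair(source, target, cfg, voxel)
        transforms.append(T)
        target = concat_clouds([target, apply_transform(source, T)])
    return target, transforms
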