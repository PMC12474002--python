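"""Dataset construction: RGB-D back-projection, variant building, sampling, splits.

A labeled tree model spawns ten training-ready variants: the original
cloud, a centered-and-normalized copy, and eight voxelizations (2.5 mm to
2 cm) of the normalized copy with labels propagated by per-voxel majority
vote (ties resolve to "pruned", which preserves thin pruned branches at
coarse resolutions).  Point sampling draws ``npoints`` indices uniformly
with replacement, and train/validation/test splits are made at the tree
level from a seeded shuffle with floor/floor/remainder sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cloud import LabeledCloud, PointCloud, write_ply
from .annotation import write_labels_csv
from .registration import voxel_groups

__all__ = [
    "CameraIntrinsics",
    "DatasetVariantSpec",
    "DEFAULT_VOXEL_SIZES",
    "depth_to_cloud",
    "cloud_to_depth",
    "center_cloud",
    "normalize_cloud",
    "voxelize_labeled",
    "sample_points",
    "split_dataset",
    "build_variants",
]

DEFAULT_VOXEL_SIZES = (0.0025, 0.005, 0.0075, 0.010, 0.0125, 0.015, 0.0175, 0.020)


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics; depth images store depth / depth_scale (mm by default)."""

    fx: float = 570.0
    fy: float = 570.0
    cx: float = 319.5
    cy: float = 239.5
    depth_scale: float = 0.001
    width: int = 640
    height: int = 480

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be > 0")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be > 0")


@dataclass(frozen=True)
class DatasetVariantSpec:
    """Controls of :func:`build_variants`.

    ``npoints_policy`` is "min", "max" or an integer — the fixed number of
    points a consumer network samples per cloud (recorded in the manifest;
    sampling itself happens at load time via :func:`sample_points`).
    """

    center: bool = True
    normalize: bool = True
    voxel_sizes: tuple[float, ...] = DEFAULT_VOXEL_SIZES
    npoints_policy: str | int = "min"
    split_ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 42

    def __post_init__(self) -> None:
        vs = tuple(float(v) for v in self.voxel_sizes)
        object.__setattr__(self, "voxel_sizes", vs)
        if any(v <= 0 for v in vs) or list(vs) != sorted(vs) or len(set(vs)) != len(vs):
            raise ValueError("voxel_sizes must be strictly positive and ascending")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if isinstance(self.npoints_policy, str) and self.npoints_policy not in ("min", "max"):
            raise ValueError("npoints_policy must be 'min', 'max' or an integer")


# ---------------------------------------------------------------------------
# RGB-D conversion


def depth_to_cloud(depth_image: np.ndarray, rgb_image: np.ndarray | None, K: CameraIntrinsics) -> PointCloud:
    """Back-project a depth image through the pinhole model.

    x = (u - cx) z / fx, y = (v - cy) z / fy, z = depth * depth_scale.
    Pixels with zero or invalid depth are dropped; colors are attached when
    an RGB image of matching size is given.
    """
    depth = np.asarray(depth_image)
    if depth.shape != (K.height, K.width):
        raise ValueError("depth image dimensions do not match intrinsics")
    if rgb_image is not None:
        rgb = np.asarray(rgb_image)
        if rgb.shape[:2] != depth.shape:
            raise ValueError("rgb and depth image dimensions differ")
    z = depth.astype(np.float64) * K.depth_scale
    valid = np.isfinite(z) & (z > 0)
    v, u = np.nonzero(valid)
    zv = z[valid]
    x = (u - K.cx) * zv / K.fx
    y = (v - K.cy) * zv / K.fy
    colors = None
    if rgb_image is not None:
        colors = rgb[v, u, :3].astype(np.uint8)
    return PointCloud(points=np.column_stack([x, y, zv]), colors=colors)


def cloud_to_depth(cloud: PointCloud, K: CameraIntrinsics) -> tuple[np.ndarray, np.ndarray]:
    """Forward-project a camera-frame cloud into (depth uint16, rgb uint8) images.

    Nearest point wins each pixel (z-buffer).  The inverse of
    :func:`depth_to_cloud` up to depth quantization and pixel collisions.
    """
    pts = cloud.points
    depth = np.zeros((K.height, K.width), dtype=np.uint16)
    rgb = np.zeros((K.height, K.width, 3), dtype=np.uint8)
    z = pts[:, 2]
    front = z > 0
    u = np.round(pts[front, 0] * K.fx / z[front] + K.cx).astype(int)
    v = np.round(pts[front, 1] * K.fy / z[front] + K.cy).astype(int)
    inside = (u >= 0) & (u < K.width) & (v >= 0) & (v < K.height)
    idx = np.flatnonzero(front)[inside]
    u, v = u[inside], v[inside]
    order = np.argsort(-z[idx], kind="stable")  # far first so near overwrites
    u, v, idx = u[order], v[order], idx[order]
    counts = np.round(z[idx] / K.depth_scale).astype(np.uint64)
    depth[v, u] = np.minimum(counts, np.iinfo(np.uint16).max).astype(np.uint16)
    if cloud.colors is not None:
        rgb[v, u] = cloud.colors[idx]
    return depth, rgb


# ---------------------------------------------------------------------------
# normalization and voxelization


def center_cloud(P):
    """Subtract the centroid; counts, labels and colors are untouched."""
    pts = P.points if hasattr(P, "points") else np.asarray(P, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("cannot center an empty cloud")
    shifted = pts - pts.mean(axis=0)
    return P.with_points(shifted) if hasattr(P, "with_points") else shifted


def normalize_cloud(P):
    """Center, then scale so the farthest point sits at unit radius."""
    centered = center_cloud(P)
    pts = centered.points if hasattr(centered, "points") else centered
    r = np.linalg.norm(pts, axis=1).max()
    if r <= 0:
        return centered
    scaled = pts / r
    return centered.with_points(scaled) if hasattr(centered, "with_points") else scaled


def voxelize_labeled(cloud: LabeledCloud, voxel: float) -> LabeledCloud:
    """Per-voxel centroids with majority-vote labels (ties resolve to pruned)."""
    if voxel <= 0:
        raise ValueError("voxel size must be > 0")
    inverse, n_vox = voxel_groups(cloud.points, voxel)
    counts = np.bincount(inverse, minlength=n_vox).astype(float)
    centroids = np.zeros((n_vox, 3))
    for k in range(3):
        centroids[:, k] = np.bincount(inverse, weights=cloud.points[:, k], minlength=n_vox) / counts
    positives = np.bincount(inverse, weights=cloud.labels.astype(float), minlength=n_vox)
    labels = (2.0 * positives >= counts).astype(np.uint8)
    colors = None
    if cloud.colors is not None:
        colors = np.zeros((n_vox, 3), dtype=np.uint8)
        for k in range(3):
            colors[:, k] = np.round(
                np.bincount(inverse, weights=cloud.colors[:, k].astype(float), minlength=n_vox) / counts
            ).astype(np.uint8)
    return LabeledCloud(points=centroids, colors=colors, labels=labels)


def sample_points(cloud: LabeledCloud, npoints: int, seed: int = 0) -> LabeledCloud:
    """Draw exactly ``npoints`` indices uniformly with replacement.

    Replacement applies regardless of the cloud size (clouds smaller than
    ``npoints`` repeat points; larger clouds may also repeat), so the draw
    distribution is the same in both regimes.  ``replace=False`` sampling
    is available via :func:`sample_points_without_replacement`.
    """
    if len(cloud) == 0:
        raise ValueError("cannot sample from an empty cloud")
    if npoints < 1:
        raise ValueError("npoints must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cloud), size=npoints, replace=True)
    return cloud.select(idx)


def sample_points_without_replacement(cloud: LabeledCloud, npoints: int, seed: int = 0) -> LabeledCloud:
    if npoints > len(cloud):
        raise ValueError("npoints exceeds cloud size for replace=False sampling")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cloud), size=npoints, replace=False)
    return cloud.select(idx)


def split_dataset(n: int, ratios: tuple[float, float, float] = (0.7, 0.1, 0.2), seed: int = 42):
    """Seeded tree-level split: floor(r_train n), floor(r_val n), remainder.

    Returns (train, val, test) index arrays — disjoint and exhaustive.
    """
    if n < 3:
        raise ValueError("need at least 3 instances to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(ratios[0] * n + 1e-9))
    n_val = int(np.floor(ratios[1] * n + 1e-9))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


# ---------------------------------------------------------------------------
# variant building


def _variant_names(spec: DatasetVariantSpec) -> list[str]:
    names = ["original", "normalized_centered_model"]
    names += [f"voxelized_model_{v:.4f}" for v in spec.voxel_sizes]
    return names


def build_variants(models: dict[str, LabeledCloud], spec: DatasetVariantSpec, out_dir: str | Path) -> dict:
    """Write the ten dataset variants of every model and a JSON manifest.

    Layout: ``<out_dir>/<variant>/<tree>.ply`` plus one ``labels.csv`` per
    variant.  The manifest records per-variant min/max point counts and the
    seeded tree-level split over the sorted model names.
    """
    if not models:
        raise ValueError("no models given")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = sorted(models)
    variants: dict[str, dict[str, LabeledCloud]] = {v: {} for v in _variant_names(spec)}
    for name in names:
        cloud = models[name]
        variants["original"][name] = cloud
        norm = cloud
        if spec.center or spec.normalize:
            norm = normalize_cloud(cloud) if spec.normalize else center_cloud(cloud)
        variants["normalized_centered_model"][name] = norm
        for v in spec.voxel_sizes:
            variants[f"voxelized_model_{v:.4f}"][name] = voxelize_labeled(norm, v)

    manifest: dict = {"variants": {}, "n_models": len(names), "model_names": names}
    for vname, clouds in variants.items():
        vdir = out_dir / vname
        vdir.mkdir(exist_ok=True)
        entries = []
        voxel = float(vname.rsplit("_", 1)[1]) if vname.startswith("voxelized") else None
        for name in names:
            write_ply(vdir / f"{name}.ply", clouds[name])
            entries.append((voxel, name, clouds[name].labels))
        write_labels_csv(entries, vdir / "labels.csv")
        sizes = [len(clouds[name]) for name in names]
        manifest["variants"][vname] = {"min_points": int(min(sizes)), "max_points": int(max(sizes))}

    if len(names) >= 3:
        train, val, test = split_dataset(len(names), spec.split_ratios, spec.seed)
        manifest["split"] = {
            "seed": spec.seed,
            "train": [names[i] for i in sorted(train)],
            "val": [names[i] for i in sorted(val)],
            "test": [names[i] for i in sorted(test)],
        }
    sizes_all = {v: manifest["variants"][v] for v in manifest["variants"]}
    if isinstance(spec.npoints_policy, int):
        manifest["npoints"] = spec.npoints_policy
    else:
        key = "min_points" if spec.npoints_policy == "min" else "max_points"
        agg = min if spec.npoints_policy == "min" else max
        manifest["npoints"] = int(agg(entry[key] for entry in sizes_all.values()))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
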