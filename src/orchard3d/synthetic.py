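"""Procedural orchard scenes with ground truth for every pipeline stage.

World frame: Y up, ground at y = 0, the tree trunk at the lateral origin and
the (virtual) camera row on the negative-Z side.  A scene is a tree
(trunk + straight cylindrical branches), a grass band at the bottom,
optionally a horizontal trellis wire and distant background clutter.  Every
point carries a component tag, a branch id and a "prunable" flag, so the
grass-removal, registration and annotation stages can all be scored against
exact ground truth.

Camera views use a right-handed frame with Z the depth away from the camera
and Y pointing down in the image, the convention of depth-sensor point
clouds; the preprocessing stage's reorientation undoes it (a 180 deg
rotation about Z restores Y-up).

Defaults emulate a dormant pear-orchard row: trees about 2 m tall and at
most ~1.5 m wide, a grass band about 0.4 m high, a support wire, and
clutter well behind the tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud, write_ply

__all__ = [
    "COMPONENT_TREE",
    "COMPONENT_GRASS",
    "COMPONENT_WIRE",
    "COMPONENT_BACKGROUND",
    "COMPONENT_NAMES",
    "TreeSpec",
    "ViewPose",
    "SceneCloud",
    "build_tree",
    "build_scene",
    "render_view",
    "simulate_pruning",
    "default_view_poses",
    "camera_axes",
    "write_scene_ply",
]

COMPONENT_TREE = 0
COMPONENT_GRASS = 1
COMPONENT_WIRE = 2
COMPONENT_BACKGROUND = 3
COMPONENT_NAMES = {
    COMPONENT_TREE: "tree",
    COMPONENT_GRASS: "grass",
    COMPONENT_WIRE: "wire",
    COMPONENT_BACKGROUND: "background",
}

#: lateral half-extent of a tree (m); trees in a trellised row stay ~1.5 m wide
MAX_LATERAL_RADIUS = 0.75

#: unsampled margin around a pruning cut (m); see docs/methods.md
CUT_COLLAR = 0.05

_GRASS_DENSITY = 2000.0  # points per m^2 of ground covered by grass
_GRASS_JITTER = 0.01  # vertical Gaussian jitter on blade tops (m)


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of one procedural tree; identical spec + seed => identical cloud."""

    trunk_height: float = 2.0
    trunk_radius: float = 0.05
    n_branches: int = 30
    branch_length_range: tuple[float, float] = (0.3, 0.9)
    branch_radius: float = 0.015
    prunable_fraction: float = 0.3
    point_density: float = 6000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trunk_height <= 0:
            raise ValueError("trunk_height must be > 0")
        if self.n_branches < 0:
            raise ValueError("n_branches must be >= 0")
        if not 0.0 <= self.prunable_fraction <= 1.0:
            raise ValueError("prunable_fraction must lie in [0, 1]")
        lo, hi = self.branch_length_range
        if not 0 < lo <= hi:
            raise ValueError("branch_length_range must be a positive (lo, hi) pair")
        if self.trunk_radius <= 0 or self.branch_radius <= 0:
            raise ValueError("radii must be > 0")
        if self.point_density <= 0:
            raise ValueError("point_density must be > 0")


@dataclass(frozen=True)
class ViewPose:
    """Camera placement for one simulated capture."""

    position: tuple[float, float, float]
    look_at: tuple[float, float, float]
    fov_deg: float = 60.0
    depth_noise_sigma: float = 0.003
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.fov_deg < 180.0:
            raise ValueError("fov_deg must lie in (0, 180)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.depth_noise_sigma < 0:
            raise ValueError("depth_noise_sigma must be >= 0")


@dataclass
class SceneCloud:
    """Labeled scene points: coordinates plus component/branch/prunable tags."""

    points: np.ndarray
    component: np.ndarray
    branch_id: np.ndarray
    prunable: np.ndarray
    colors: np.ndarray | None = None
    pose: ViewPose | None = None
    source_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        n = len(self.points)
        self.component = np.asarray(self.component, dtype=np.uint8).ravel()
        self.branch_id = np.asarray(self.branch_id, dtype=np.int32).ravel()
        self.prunable = np.asarray(self.prunable, dtype=bool).ravel()
        for name, arr in (("component", self.component), ("branch_id", self.branch_id), ("prunable", self.prunable)):
            if len(arr) != n:
                raise ValueError(f"{name} length does not match points")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != n:
                raise ValueError("colors length does not match points")
        if self.prunable.any() and not (self.component[self.prunable] == COMPONENT_TREE).all():
            raise ValueError("prunable points must be tree points")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index: np.ndarray) -> "SceneCloud":
        return SceneCloud(
            points=self.points[index],
            component=self.component[index],
            branch_id=self.branch_id[index],
            prunable=self.prunable[index],
            colors=None if self.colors is None else self.colors[index],
            pose=self.pose,
            source_indices=None if self.source_indices is None else self.source_indices[index],
        )

    def with_points(self, points: np.ndarray) -> "SceneCloud":
        if len(points) != len(self):
            raise ValueError("replacement coordinates must match point count")
        out = self.select(slice(None))
        out.points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        return out

    def to_cloud(self) -> PointCloud:
        """Pack tags into a generic :class:`PointCloud` (PLY-serializable)."""
        return PointCloud(
            points=self.points.copy(),
            colors=None if self.colors is None else self.colors.copy(),
            attrs={
                "component": self.component.copy(),
                "branch_id": self.branch_id.copy(),
                "prunable": self.prunable.astype(np.uint8),
            },
        )

    @staticmethod
    def from_cloud(cloud: PointCloud) -> "SceneCloud":
        return SceneCloud(
            points=cloud.points,
            component=cloud.attrs["component"],
            branch_id=cloud.attrs["branch_id"],
            prunable=cloud.attrs["prunable"].astype(bool),
            colors=cloud.colors,
        )

    @staticmethod
    def concat(parts: list["SceneCloud"]) -> "SceneCloud":
        colors_ok = all(p.colors is not None for p in parts)
        return SceneCloud(
            points=np.concatenate([p.points for p in parts]),
            component=np.concatenate([p.component for p in parts]),
            branch_id=np.concatenate([p.branch_id for p in parts]),
            prunable=np.concatenate([p.prunable for p in parts]),
            colors=np.concatenate([p.colors for p in parts]) if colors_ok else None,
        )


def _cylinder_points(rng, start, direction, length, radius, density):
    """Uniform sample on the lateral surface of a cylinder."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    area = 2.0 * np.pi * radius * length
    n = max(int(round(density * area)), 1)
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0]) if abs(direction[0]) < 0.9 else np.array([0.0, 0.0, 1.0])
    u = np.cross(direction, helper)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    s = rng.uniform(0.0, length, n)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    pts = (
        np.asarray(start, dtype=float)
        + s[:, None] * direction
        + radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
    )
    return pts


def _tree_colors(rng, n):
    base = np.array([115, 82, 58], dtype=float)  # bark brown
    jitter = rng.integers(-18, 19, size=(n, 3))
    return np.clip(base + jitter, 0, 255).astype(np.uint8)


def build_tree(spec: TreeSpec) -> SceneCloud:
    """Sample a trunk-plus-branches tree as a labeled point cloud.

    Branch ids: 0 is the trunk, 1..n_branches the branches.  The
    ``prunable_fraction`` of branches ranked longest-and-most-vertical are
    flagged prunable — in a trellised pear row the pruner removes the long
    vertical water shoots, and that is the structure a downstream predictor
    is expected to learn.
    """
    rng = np.random.default_rng(spec.seed)
    parts = []

    trunk = _cylinder_points(rng, (0, 0, 0), (0, 1, 0), spec.trunk_height, spec.trunk_radius, spec.point_density)
    parts.append((trunk, 0, False))

    # branch skeletons: attachment height, azimuth, upward elevation
    attach_y = rng.uniform(0.5 * spec.trunk_height, 0.95 * spec.trunk_height, spec.n_branches)
    azimuth = rng.uniform(0.0, 2.0 * np.pi, spec.n_branches)
    elevation = np.deg2rad(rng.uniform(20.0, 80.0, spec.n_branches))
    length = rng.uniform(*spec.branch_length_range, spec.n_branches)

    dirs = np.column_stack(
        [
            np.cos(elevation) * np.cos(azimuth),
            np.sin(elevation),
            np.cos(elevation) * np.sin(azimuth),
        ]
    )
    starts = np.column_stack(
        [
            spec.trunk_radius * np.cos(azimuth),
            attach_y,
            spec.trunk_radius * np.sin(azimuth),
        ]
    )
    # clip lengths so branch tips stay within the row's lateral envelope
    for b in range(spec.n_branches):
        lat = np.hypot(dirs[b, 0], dirs[b, 2])
        if lat > 1e-9:
            room = (MAX_LATERAL_RADIUS - spec.trunk_radius - spec.branch_radius) / lat
            length[b] = min(length[b], room)

    score = length * dirs[:, 1]  # long * vertical
    n_prunable = int(round(spec.prunable_fraction * spec.n_branches))
    prunable_ids = set()
    if n_prunable > 0:
        order = np.argsort(-score, kind="stable")
        prunable_ids = set((order[:n_prunable] + 1).tolist())

    for b in range(spec.n_branches):
        pts = _cylinder_points(rng, starts[b], dirs[b], length[b], spec.branch_radius, spec.point_density)
        parts.append((pts, b + 1, (b + 1) in prunable_ids))

    points = np.concatenate([p for p, _, _ in parts])
    branch_id = np.concatenate([np.full(len(p), bid, dtype=np.int32) for p, bid, _ in parts])
    prunable = np.concatenate([np.full(len(p), flag, dtype=bool) for p, _, flag in parts])
    return SceneCloud(
        points=points,
        component=np.full(len(points), COMPONENT_TREE, dtype=np.uint8),
        branch_id=branch_id,
        prunable=prunable,
        colors=_tree_colors(rng, len(points)),
    )


def build_scene(
    tree: SceneCloud,
    grass_height: float = 0.4,
    grass_extent: float = 3.0,
    wire: bool = True,
    background: bool = True,
    seed: int = 0,
) -> SceneCloud:
    """Drop the tree into a scene: grass band, optional wire and clutter.

    Grass blades have tops at ``grass_height * Beta(1, 3)`` above the ground
    plus ~1 cm of Gaussian jitter — dense near the soil and thinning toward
    the tips, so the band spans roughly ``grass_height`` while a dominant
    near-horizontal plane exists at its base.
    """
    if grass_height < 0:
        raise ValueError("grass_height must be >= 0")
    rng = np.random.default_rng(seed)
    parts = [tree]

    if grass_height > 0:
        depth_span = 2.0
        n = int(round(_GRASS_DENSITY * grass_extent * depth_span))
        x = rng.uniform(-grass_extent / 2.0, grass_extent / 2.0, n)
        z = rng.uniform(-depth_span / 2.0, depth_span / 2.0, n)
        y = grass_height * rng.beta(1.0, 3.0, n) + rng.normal(0.0, _GRASS_JITTER, n)
        pts = np.column_stack([x, y, z])
        greens = np.clip(
            np.column_stack([rng.integers(40, 90, n), rng.integers(110, 170, n), rng.integers(30, 70, n)]), 0, 255
        ).astype(np.uint8)
        parts.append(_scene_part(pts, COMPONENT_GRASS, greens))

    if wire:
        n = 300
        x = rng.uniform(-grass_extent / 2.0, grass_extent / 2.0, n)
        y = 0.8 + rng.normal(0.0, 0.002, n)
        z = 0.1 + rng.normal(0.0, 0.002, n)
        pts = np.column_stack([x, y, z])
        gray = np.full((n, 3), 140, dtype=np.uint8)
        parts.append(_scene_part(pts, COMPONENT_WIRE, gray))

    if background:
        # distant clutter (neighboring row, terrain) well behind the tree
        n = 1500
        x = rng.uniform(-grass_extent / 2.0, grass_extent / 2.0, n)
        y = rng.uniform(0.0, 2.5, n)
        z = rng.uniform(2.5, 4.0, n)
        pts = np.column_stack([x, y, z])
        drab = np.clip(
            np.column_stack([rng.integers(60, 110, n), rng.integers(70, 120, n), rng.integers(50, 100, n)]), 0, 255
        ).astype(np.uint8)
        parts.append(_scene_part(pts, COMPONENT_BACKGROUND, drab))

    if len(parts) == 1:
        return tree.select(slice(None))
    return SceneCloud.concat(parts)


def _scene_part(points, component, colors):
    n = len(points)
    return SceneCloud(
        points=points,
        component=np.full(n, component, dtype=np.uint8),
        branch_id=np.full(n, -1, dtype=np.int32),
        prunable=np.zeros(n, dtype=bool),
        colors=colors,
    )


def camera_axes(pose: ViewPose) -> tuple[np.ndarray, np.ndarray]:
    """World-to-camera rotation (rows = camera axes) and camera position.

    Camera frame: X right in the image, Y down, Z the viewing direction
    (right-handed, x cross y = z).
    """
    position = np.asarray(pose.position, dtype=float)
    forward = np.asarray(pose.look_at, dtype=float) - position
    norm = np.linalg.norm(forward)
    if norm < 1e-12:
        raise ValueError("camera position and look_at coincide")
    z_cam = forward / norm
    world_up = np.array([0.0, 1.0, 0.0])
    x_cam = np.cross(z_cam, world_up)
    if np.linalg.norm(x_cam) < 1e-9:  # looking straight up/down
        x_cam = np.array([1.0, 0.0, 0.0])
    x_cam = x_cam / np.linalg.norm(x_cam)
    y_cam = np.cross(z_cam, x_cam)
    R = np.vstack([x_cam, y_cam, z_cam])
    return R, position


def render_view(scene: SceneCloud, pose: ViewPose, seed: int = 0) -> SceneCloud:
    """Simulate one capture: frustum cull, camera-frame transform, noise.

    The returned cloud is expressed in the camera frame (Z = depth, Y = image
    vertical/down), carries the ground-truth ``pose`` and the indices of the
    selected scene points for oracle checks, has Gaussian depth noise of
    ``pose.depth_noise_sigma`` and Bernoulli dropout at ``pose.dropout_rate``.
    An empty frustum yields an empty cloud, not an error.
    """
    if len(scene) == 0:
        raise ValueError("scene is empty")
    rng = np.random.default_rng(seed)
    R, position = camera_axes(pose)
    cam = (scene.points - position) @ R.T
    half = np.tan(np.deg2rad(pose.fov_deg) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        visible = (
            (cam[:, 2] > 1e-9)
            & (np.abs(cam[:, 0] / cam[:, 2]) <= half)
            & (np.abs(cam[:, 1] / cam[:, 2]) <= half)
        )
    idx = np.flatnonzero(visible)
    if pose.dropout_rate > 0 and len(idx):
        keep = rng.random(len(idx)) >= pose.dropout_rate
        idx = idx[keep]
    view = scene.select(idx)
    pts = cam[idx]
    if pose.depth_noise_sigma > 0 and len(pts):
        pts = pts.copy()
        pts[:, 2] += rng.normal(0.0, pose.depth_noise_sigma, len(pts))
    view.points = pts
    view.pose = pose
    view.source_indices = idx
    return view


def default_view_poses(
    target: tuple[float, float, float] = (0.0, 1.0, 0.0),
    distance: float = 2.8,
    fov_deg: float = 60.0,
    depth_noise_sigma: float = 0.003,
    dropout_rate: float = 0.1,
) -> list[ViewPose]:
    """Four partially overlapping front-side viewpoints.

    Mid-left, center, mid-right and center-upper placements along the
    camera row — the capture pattern of a trellised orchard where wires
    prevent walking around the tree.
    """
    tx, ty, tz = target
    positions = [
        (tx - 1.2, ty + 0.2, tz - distance + 0.2),
        (tx, ty + 0.2, tz - distance),
        (tx + 1.2, ty + 0.2, tz - distance + 0.2),
        (tx, ty + 1.0, tz - distance + 0.2),
    ]
    return [
        ViewPose(
            position=p,
            look_at=target,
            fov_deg=fov_deg,
            depth_noise_sigma=depth_noise_sigma,
            dropout_rate=dropout_rate,
        )
        for p in positions
    ]


def simulate_pruning(scene: SceneCloud, seed: int = 0) -> tuple[SceneCloud, SceneCloud, np.ndarray]:
    """Remove every prunable branch; return (pre, post, truth-on-pre).

    ``post`` is ``pre`` minus all points of the prunable branches and
    ``truth`` marks exactly the removed points on ``pre`` — the pre cloud is
    an exact partition into post-surviving and truth-marked points.  Removed
    points within :data:`CUT_COLLAR` of retained geometry are dropped from
    the pre cloud altogether (the cut collar stays on the tree and the
    junction region is unresolved at sensor scale), so the removed structure
    is geometrically separated from the survivor.
    """
    del seed  # selection is currently exhaustive; kept for interface stability
    if not scene.prunable.any():
        raise ValueError("scene has no prunable branches")
    removed = scene.prunable
    survivors = scene.select(~removed)
    removed_pts = scene.points[removed]
    dist, _ = cKDTree(survivors.points).query(removed_pts, k=1)
    collar = dist <= CUT_COLLAR
    drop = np.zeros(len(scene), dtype=bool)
    drop[np.flatnonzero(removed)[collar]] = True
    pre = scene.select(~drop)
    truth = pre.prunable.copy()
    post = pre.select(~truth)
    return pre, post, truth


def write_scene_ply(path: str | Path, scene: SceneCloud, binary: bool = True) -> None:
    """Write a scene/view as PLY plus a JSON pose sidecar when available."""
    path = Path(path)
    write_ply(path, scene.to_cloud(), binary=binary)
    if scene.pose is not None:
        R, position = camera_axes(scene.pose)
        sidecar = {
            "position": list(scene.pose.position),
            "look_at": list(scene.pose.look_at),
            "fov_deg": scene.pose.fov_deg,
            "depth_noise_sigma": scene.pose.depth_noise_sigma,
            "dropout_rate": scene.pose.dropout_rate,
            "world_to_camera_rotation": R.tolist(),
            "camera_position": position.tolist(),
        }
        path.with_suffix(".pose.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def view_to_target_transform(view_pose: ViewPose, target_pose: ViewPose) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth rigid transform mapping ``view_pose``'s camera frame into
    ``target_pose``'s camera frame (the oracle for registration checks)."""
    R_v, p_v = camera_axes(view_pose)
    R_t, p_t = camera_axes(target_pose)
    R = R_t @ R_v.T
    t = R_t @ (p_v - p_t)
    return R, t


# re-exported convenience: a tweaked copy of a spec
def with_seed(spec: TreeSpec, seed: int) -> TreeSpec:
    return replace(spec, seed=seed)
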