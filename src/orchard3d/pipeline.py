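"""End-to-end orchestration: simulate -> preprocess -> register -> annotate ->
build-dataset -> evaluate, from a single config with one global seed.

The output tree mirrors a field-capture archive: ``B/`` (before pruning)
and ``A/`` (after pruning) hold an ``E1`` session folder with one
directory per tree (``tree_<row>_V_<iteration>``) containing
``original_images/`` (per-view PLY, optional depth/RGB PNG),
``filtered_noGrass/`` (preprocessed views) and ``reconstruction/`` (the
merged model); ``Merged/`` holds the labeled pre/post overlap and the
label CSV.  The global seed is forked deterministically into per-stage
seeds so reruns are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .annotation import AnnotationConfig, annotated_merged_cloud, label_pruned, write_labels_csv
from .cloud import PointCloud, write_ply
from .dataset import CameraIntrinsics, DatasetVariantSpec, build_variants, cloud_to_depth
from .evaluation import confusion, metrics, reconstruction_summary
from .preprocessing import PreprocessConfig, cull_background, remove_grass, reorient
from .registration import (
    RobustSolverConfig,
    apply_transform,
    register_pair,
    rotation_geodesic_deg,
    sequential_register,
)
from .synthetic import SceneCloud, TreeSpec

logger = logging.getLogger("orchard3d")

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

REQUIRED_SECTIONS = ("simulate", "preprocess", "register", "annotate", "dataset")

# pose-error bounds used to score a registration against the synthetic
# ground-truth pose (the field workflow relies on visual inspection instead)
SUCCESS_ROT_DEG = 2.0
SUCCESS_TRANS_M = 0.04


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_dict``)."""

    seed: int = 0
    out_root: Path = Path("runs/out")
    n_trees: int = 3
    tree: TreeSpec = field(default_factory=TreeSpec)
    grass_height: float = 0.4
    grass_extent: float = 3.0
    wire: bool = True
    background: bool = True
    depth_noise_sigma: float = 0.003
    dropout_rate: float = 0.1
    write_images: bool = False
    rot_z_deg: float = 180.0
    rot_y_deg: float = 0.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    voxel: float = 0.02
    solver: RobustSolverConfig = field(default_factory=RobustSolverConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    dataset: DatasetVariantSpec = field(default_factory=DatasetVariantSpec)
    intrinsics: CameraIntrinsics = field(default_factory=CameraIntrinsics)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        for section in REQUIRED_SECTIONS:
            if section not in raw:
                raise ConfigError(f"config is missing required section {section!r}")
        sim = dict(raw["simulate"])
        pre = dict(raw["preprocess"])
        reg = dict(raw["register"])
        ann = dict(raw["annotate"])
        ds = dict(raw["dataset"])
        try:
            tree = TreeSpec(**sim.pop("tree", {}))
            cfg = RunConfig(
                seed=int(raw.get("seed", 0)),
                out_root=Path(raw.get("out", "runs/out")),
                n_trees=int(sim.pop("n_trees", 3)),
                tree=tree,
                grass_height=float(sim.pop("grass_height", 0.4)),
                grass_extent=float(sim.pop("grass_extent", 3.0)),
                wire=bool(sim.pop("wire", True)),
                background=bool(sim.pop("background", True)),
                depth_noise_sigma=float(sim.pop("depth_noise_sigma", 0.003)),
                dropout_rate=float(sim.pop("dropout_rate", 0.1)),
                write_images=bool(sim.pop("write_images", False)),
                rot_z_deg=float(pre.pop("rot_z_deg", 180.0)),
                rot_y_deg=float(pre.pop("rot_y_deg", 0.0)),
                preprocess=PreprocessConfig(**pre),
                voxel=float(reg.pop("voxel", 0.02)),
                solver=RobustSolverConfig(**reg),
                annotation=AnnotationConfig(**ann),
                dataset=DatasetVariantSpec(**{**ds, "voxel_sizes": tuple(ds.get("voxel_sizes", synthetic_default_voxels()))}),
            )
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        if sim:
            raise ConfigError(f"unknown keys in 'simulate' section: {sorted(sim)}")
        return cfg

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        return RunConfig.from_dict(raw)


def synthetic_default_voxels() -> tuple[float, ...]:
    from .dataset import DEFAULT_VOXEL_SIZES

    return DEFAULT_VOXEL_SIZES


def _stage_seed(root_seed: int, tree_index: int, stage: int) -> int:
    """Deterministic per-tree, per-stage seed below 2**31."""
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(tree_index, stage))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _tree_dirs(root: Path, side: str, name: str) -> dict[str, Path]:
    base = root / side / "E1" / name
    dirs = {
        "base": base,
        "original_images": base / "original_images",
        "filtered_noGrass": base / "filtered_noGrass",
        "reconstruction": base / "reconstruction",
    }
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)
    return dirs


def _preprocess_view(view: SceneCloud, cfg: RunConfig, seed: int) -> SceneCloud:
    upright = reorient(view, cfg.rot_z_deg, cfg.rot_y_deg)
    culled = cull_background(upright, cfg.preprocess)
    return remove_grass(culled, cfg.preprocess, seed=seed)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage on synthetic trees; returns (and writes) the manifest."""
    t_start = time.time()
    root = cfg.out_root
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "trees": {}, "stages": [], "files": []}
    poses = synthetic.default_view_poses(
        depth_noise_sigma=cfg.depth_noise_sigma, dropout_rate=cfg.dropout_rate
    )

    labeled_models: dict[str, object] = {}
    truth_by_tree: dict[str, np.ndarray] = {}
    pred_by_tree: dict[str, np.ndarray] = {}
    reg_success = {"pre": 0, "post": 0, "both": 0, "annotated": 0}

    for i in range(cfg.n_trees):
        name = f"tree_1_V_{i + 1}"
        info: dict = {}
        logger.info("[%s] simulate", name)
        tree = synthetic.build_tree(dataclasses.replace(cfg.tree, seed=_stage_seed(cfg.seed, i, 0)))
        scene = synthetic.build_scene(
            tree,
            grass_height=cfg.grass_height,
            grass_extent=cfg.grass_extent,
            wire=cfg.wire,
            background=cfg.background,
            seed=_stage_seed(cfg.seed, i, 1),
        )
        pre_scene, post_scene, _ = synthetic.simulate_pruning(scene, seed=_stage_seed(cfg.seed, i, 2))

        models: dict[str, PointCloud] = {}
        side_ok: dict[str, bool] = {}
        for side, src in (("B", pre_scene), ("A", post_scene)):
            dirs = _tree_dirs(root, side, name)
            views = []
            for v, pose in enumerate(poses):
                view = synthetic.render_view(src, pose, seed=_stage_seed(cfg.seed, i, 10 + 10 * v + (0 if side == "B" else 5)))
                synthetic.write_scene_ply(dirs["original_images"] / f"view_{v}.ply", view)
                if cfg.write_images:
                    import imageio.v3 as iio

                    depth, rgb = cloud_to_depth(view.to_cloud(), cfg.intrinsics)
                    iio.imwrite(dirs["original_images"] / f"view_{v}_depth.png", depth)
                    iio.imwrite(dirs["original_images"] / f"view_{v}_rgb.png", rgb)
                clean = _preprocess_view(view, cfg, seed=_stage_seed(cfg.seed, i, 100 + v))
                logger.info("[%s/%s] view %d: %d -> %d points after preprocessing", name, side, v, len(view), len(clean))
                synthetic.write_scene_ply(dirs["filtered_noGrass"] / f"view_{v}.ply", clean)
                views.append(clean)
            merged, transforms = sequential_register(views, cfg.solver, cfg.voxel)
            write_ply(dirs["reconstruction"] / "model.ply", merged)
            (dirs["reconstruction"] / "transforms.json").write_text(
                json.dumps([T.matrix().tolist() for T in transforms], indent=2)
            )
            models[side] = merged
            # score against ground-truth poses (synthetic oracle; the field
            # workflow judges this step by eye)
            ok = True
            for k, T in enumerate(transforms, start=1):
                R_true, t_true = _true_view_transform(views[k], views[0], cfg)
                rot_err = rotation_geodesic_deg(T.R, R_true)
                trans_err = float(np.linalg.norm(T.t - t_true))
                ok &= rot_err < SUCCESS_ROT_DEG and trans_err < SUCCESS_TRANS_M
            side_ok[side] = ok
            info[f"registration_ok_{side}"] = ok
            info[f"n_points_{side}"] = len(merged)

        reg_success["pre"] += side_ok["B"]
        reg_success["post"] += side_ok["A"]
        both = side_ok["B"] and side_ok["A"]
        reg_success["both"] += both

        logger.info("[%s] annotate", name)
        merged_dir = root / "Merged" / "E1" / name
        merged_dir.mkdir(parents=True, exist_ok=True)
        T_ann, _diag = register_pair(models["A"], models["B"], cfg.solver, cfg.annotation.voxel)
        post_aligned = apply_transform(models["A"], T_ann)
        labeled = label_pruned(models["B"], post_aligned, cfg.annotation)
        write_ply(merged_dir / "labeled_pre.ply", labeled)
        write_ply(merged_dir / "overlap.ply", annotated_merged_cloud(labeled, post_aligned))
        truth = models["B"].attrs["prunable"].astype(np.uint8)
        truth_by_tree[name] = truth
        pred_by_tree[name] = labeled.labels
        rep = metrics(confusion(truth, labeled.labels))
        info["annotation"] = dataclasses.asdict(rep)
        ann_ok = both and rep.f1 >= 0.5
        reg_success["annotated"] += ann_ok
        from .cloud import LabeledCloud

        labeled_models[name] = LabeledCloud(points=labeled.points, colors=labeled.colors, labels=labeled.labels)
        manifest["trees"][name] = info

    logger.info("build dataset variants")
    ds_manifest = build_variants(labeled_models, cfg.dataset, root / "dataset")
    write_labels_csv(
        [(None, name, pred_by_tree[name]) for name in sorted(pred_by_tree)],
        root / "Merged" / "labels.csv",
    )

    summary = reconstruction_summary(
        reg_success["pre"], reg_success["post"], reg_success["both"], reg_success["annotated"], cfg.n_trees
    )
    manifest["stages"] = ["simulate", "preprocess", "register", "annotate", "build_dataset", "evaluate"]
    manifest["dataset"] = ds_manifest
    manifest["reconstruction_summary"] = {
        "counts": summary.loc["count"].astype(int).to_dict(),
        "percent": summary.loc["percent"].to_dict(),
        "total": cfg.n_trees,
    }
    # timing is logged, not written: manifest files must be bit-reproducible
    logger.info("pipeline finished in %.1f s", time.time() - t_start)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _true_view_transform(view: SceneCloud, target_view: SceneCloud, cfg: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth transform between two preprocessed (reoriented) views."""
    R_vt, t_vt = synthetic.view_to_target_transform(view.pose, target_view.pose)
    # preprocessing reorients both frames by the same rotation Q: the
    # ground-truth transform conjugates accordingly.
    Q = _reorient_matrix(cfg.rot_z_deg, cfg.rot_y_deg)
    return Q @ R_vt @ Q.T, Q @ t_vt


def _reorient_matrix(rot_z_deg: float, rot_y_deg: float) -> np.ndarray:
    cz, sz = np.cos(np.deg2rad(rot_z_deg)), np.sin(np.deg2rad(rot_z_deg))
    cy, sy = np.cos(np.deg2rad(rot_y_deg)), np.sin(np.deg2rad(rot_y_deg))
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    Ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    return Ry @ Rz
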