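"""Change-detection labeling of pruned branches.

A tree is modeled before pruning (cloud ``Pb``) and after (``Pa``).  Once
the post model is registered onto the pre model, any pre-model point whose
nearest neighbor in the aligned post model lies farther than a threshold
tau (default 0.03 m, on the order of registration noise) must belong to
wood that was removed — it is labeled 1 (pruned).  The comparison is
strict (d > tau).  False labels from occlusion or clutter present in only
one model are a known limitation of the approach; no semantic filtering is
attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .cloud import LabeledCloud, PointCloud
from .registration import RigidTransform, RobustSolverConfig, apply_transform, register_pair

__all__ = [
    "AnnotationConfig",
    "nn_distances",
    "label_pruned",
    "merge_and_annotate",
    "write_labels_csv",
    "read_labels_csv",
    "PRUNED_COLOR",
]

#: positives are painted yellow in exported clouds
PRUNED_COLOR = np.array([255, 220, 0], dtype=np.uint8)


@dataclass(frozen=True)
class AnnotationConfig:
    """tau: nearest-neighbor distance (m) beyond which a point counts as pruned;
    voxel: downsampling size (m) for the pre/post registration step."""

    tau: float = 0.03
    voxel: float = 0.02

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.voxel <= 0:
            raise ValueError("voxel must be > 0")


def _pts(P) -> np.ndarray:
    return P.points if hasattr(P, "points") else np.asarray(P, dtype=float).reshape(-1, 3)


def nn_distances(Pb, Pa) -> np.ndarray:
    """d_i = min_j ||p_i - q_j|| for every p_i in Pb against Pa."""
    pb, pa = _pts(Pb), _pts(Pa)
    if len(pb) == 0 or len(pa) == 0:
        raise ValueError("both clouds must be nonempty")
    d, _ = cKDTree(pa).query(pb, k=1)
    return d


def label_pruned(Pb, Pa, cfg: AnnotationConfig | None = None) -> LabeledCloud:
    """Label pre-model points strictly farther than tau from the post model."""
    cfg = cfg or AnnotationConfig()
    d = nn_distances(Pb, Pa)
    labels = (d > cfg.tau).astype(np.uint8)
    pb = _pts(Pb)
    colors = getattr(Pb, "colors", None)
    if colors is not None:
        colors = colors.copy()
        colors[labels == 1] = PRUNED_COLOR
    return LabeledCloud(points=pb.copy(), colors=colors, labels=labels)


def merge_and_annotate(
    pre_model,
    post_model,
    cfg: AnnotationConfig | None = None,
    solver: RobustSolverConfig | None = None,
) -> tuple[LabeledCloud, RigidTransform]:
    """Register the post model (source) onto the pre model (target), then label.

    Reuses the single-pair registration machinery of the reconstruction
    stage at the annotation voxel size.  Labels live on the full-resolution
    pre model; the transform maps post-model coordinates into the
    pre-model frame.
    """
    cfg = cfg or AnnotationConfig()
    solver = solver or RobustSolverConfig()
    if len(_pts(pre_model)) == 0 or len(_pts(post_model)) == 0:
        raise ValueError("both models must be nonempty")
    T, _ = register_pair(post_model, pre_model, solver, cfg.voxel)
    post_aligned = apply_transform(post_model if hasattr(post_model, "with_points") else _pts(post_model), T)
    labeled = label_pruned(pre_model, post_aligned, cfg)
    return labeled, T


def write_labels_csv(entries, path: str | Path) -> None:
    """Rows of (voxel size, tree name, labels); labels serialize as '0 1 0 ...'.

    ``voxel_size`` is empty for un-voxelized (full-resolution) entries.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["voxel_size", "tree_name", "labels"])
        for voxel_size, tree_name, labels in entries:
            labels = np.asarray(labels).astype(int)
            writer.writerow(
                ["" if voxel_size is None else repr(float(voxel_size)), tree_name, " ".join(map(str, labels))]
            )


def read_labels_csv(path: str | Path) -> list[tuple[float | None, str, np.ndarray]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:3] != ["voxel_size", "tree_name", "labels"]:
            raise ValueError("unrecognized label CSV header")
        out = []
        for voxel_size, tree_name, labels in reader:
            arr = np.fromstring(labels, dtype=np.uint8, sep=" ") if labels else np.zeros(0, dtype=np.uint8)
            out.append((float(voxel_size) if voxel_size else None, tree_name, arr))
    return out


def annotated_merged_cloud(labeled: LabeledCloud, post_aligned) -> PointCloud:
    """Overlay of the labeled pre model and the aligned post model (for export)."""
    pa = _pts(post_aligned)
    pts = np.concatenate([labeled.points, pa])
    colors = None
    if labeled.colors is not None:
        post_colors = getattr(post_aligned, "colors", None)
        if post_colors is None:
            post_colors = np.full((len(pa), 3), 128, dtype=np.uint8)
        colors = np.concatenate([labeled.colors, post_colors])
    labels = np.concatenate([labeled.labels, np.zeros(len(pa), dtype=np.uint8)])
    return PointCloud(points=pts, colors=colors, labels=labels)
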