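"""Point-cloud container and PLY input/output.

The :class:`PointCloud` is the currency of the whole pipeline: an (N, 3)
array of coordinates in meters, optionally carrying per-point RGB colors,
binary pruning labels, and arbitrary named per-point attribute arrays
(e.g. the synthetic generator's ``component`` / ``branch_id`` tags, which
downstream stages use as evaluation oracles).

PLY files are read and written directly with numpy structured arrays so
that extra per-vertex properties survive a round trip bit-exactly.  Both
ASCII and binary little-endian dialects are supported; coordinates are
stored as doubles so meters round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PointCloud", "LabeledCloud", "read_ply", "write_ply", "concat_clouds"]


_PLY_TO_NUMPY = {
    "char": "i1",
    "int8": "i1",
    "uchar": "u1",
    "uint8": "u1",
    "short": "<i2",
    "int16": "<i2",
    "ushort": "<u2",
    "uint16": "<u2",
    "int": "<i4",
    "int32": "<i4",
    "uint": "<u4",
    "uint32": "<u4",
    "float": "<f4",
    "float32": "<f4",
    "double": "<f8",
    "float64": "<f8",
}

_NUMPY_TO_PLY = {
    "i1": "char",
    "u1": "uchar",
    "i2": "short",
    "u2": "ushort",
    "i4": "int",
    "u4": "uint",
    "f4": "float",
    "f8": "double",
}


@dataclass
class PointCloud:
    """N points in meters with optional colors, labels and extra attributes."""

    points: np.ndarray
    colors: np.ndarray | None = None
    labels: np.ndarray | None = None
    attrs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        n = len(self.points)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != n:
                raise ValueError("colors length does not match points")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.uint8).ravel()
            if len(self.labels) != n:
                raise ValueError("labels length does not match points")
        for name, arr in self.attrs.items():
            arr = np.asarray(arr)
            if len(arr) != n:
                raise ValueError(f"attribute {name!r} length does not match points")
            self.attrs[name] = arr

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Subset (boolean mask or integer indices); all fields follow."""
        return type(self)(
            points=self.points[index],
            colors=None if self.colors is None else self.colors[index],
            labels=None if self.labels is None else self.labels[index],
            attrs={k: v[index] for k, v in self.attrs.items()},
        )

    def with_points(self, points: np.ndarray) -> "PointCloud":
        """Same per-point data attached to new coordinates (e.g. after a rigid move)."""
        if len(points) != len(self):
            raise ValueError("replacement coordinates must match point count")
        return type(self)(
            points=np.asarray(points, dtype=np.float64),
            colors=None if self.colors is None else self.colors.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            attrs={k: v.copy() for k, v in self.attrs.items()},
        )

    def copy(self) -> "PointCloud":
        return self.select(slice(None))


class LabeledCloud(PointCloud):
    """Point cloud with a mandatory binary prune label per point (1 = pruned)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.labels is None:
            raise ValueError("LabeledCloud requires labels")
        bad = ~np.isin(self.labels, (0, 1))
        if bad.any():
            raise ValueError("labels must be binary (0/1)")


def concat_clouds(clouds: list[PointCloud]) -> PointCloud:
    """Stack clouds; optional fields are kept only when present on every input."""
    if not clouds:
        raise ValueError("nothing to concatenate")
    points = np.concatenate([c.points for c in clouds])
    colors = None
    if all(c.colors is not None for c in clouds):
        colors = np.concatenate([c.colors for c in clouds])
    labels = None
    if all(c.labels is not None for c in clouds):
        labels = np.concatenate([c.labels for c in clouds])
    common = set(clouds[0].attrs)
    for c in clouds[1:]:
        common &= set(c.attrs)
    attrs = {k: np.concatenate([c.attrs[k] for c in clouds]) for k in sorted(common)}
    return PointCloud(points=points, colors=colors, labels=labels, attrs=attrs)


def _structured_from_cloud(cloud: PointCloud) -> np.ndarray:
    fields: list[tuple[str, str]] = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
    if cloud.colors is not None:
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
    if cloud.labels is not None:
        fields += [("label", "u1")]
    for name in cloud.attrs:
        code = cloud.attrs[name].dtype.str.lstrip("<>|=")
        if code not in _NUMPY_TO_PLY:
            raise ValueError(f"attribute {name!r} has unsupported dtype {code}")
        fields.append((name, f"<{code}" if code[0] in "ifu" and code[1] != "1" else code))
    data = np.empty(len(cloud), dtype=fields)
    data["x"], data["y"], data["z"] = cloud.points.T
    if cloud.colors is not None:
        data["red"], data["green"], data["blue"] = cloud.colors.T
    if cloud.labels is not None:
        data["label"] = cloud.labels
    for name, arr in cloud.attrs.items():
        data[name] = arr
    return data


def write_ply(path: str | Path, cloud: PointCloud, binary: bool = True) -> None:
    """Write a point cloud as PLY with one vertex element.

    Colors map to ``red/green/blue`` uchar, labels to a ``label`` uchar and
    every entry of :attr:`PointCloud.attrs` to a property of matching name.
    """
    path = Path(path)
    data = _structured_from_cloud(cloud)
    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {len(data)}"]
    for name in data.dtype.names:
        code = data.dtype[name].str.lstrip("<>|=")
        header.append(f"property {_NUMPY_TO_PLY[code]} {name}")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(data.tobytes())
        else:
            cols = [data[name] for name in data.dtype.names]
            lines = []
            for row in zip(*cols):
                lines.append(" ".join(repr(v.item()) if v.dtype.kind == "f" else str(v) for v in row))
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def _parse_header(fh) -> tuple[str, int, list[tuple[str, str]]]:
    line = fh.readline().strip()
    if line != b"ply":
        raise ValueError("not a PLY file")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    while True:
        line = fh.readline()
        if not line:
            raise ValueError("truncated PLY header")
        tokens = line.decode("ascii").strip().split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            fmt = tokens[1]
        elif tokens[0] == "element":
            in_vertex = tokens[1] == "vertex"
            if in_vertex:
                n_vertex = int(tokens[2])
            elif int(tokens[2]) > 0:
                raise ValueError(f"unsupported non-empty element {tokens[1]!r}")
        elif tokens[0] == "property" and in_vertex:
            if tokens[1] == "list":
                raise ValueError("list vertex properties are not supported")
            props.append((tokens[2], tokens[1]))
        elif tokens[0] == "end_header":
            break
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValueError(f"unsupported PLY format {fmt!r}")
    if n_vertex is None:
        raise ValueError("PLY file has no vertex element")
    return fmt, n_vertex, props


def read_ply(path: str | Path) -> PointCloud:
    """Read a PLY point cloud written by :func:`write_ply` or any simple PLY."""
    with open(path, "rb") as fh:
        fmt, n, props = _parse_header(fh)
        dtype = np.dtype([(name, _PLY_TO_NUMPY[ply_t]) for name, ply_t in props])
        if fmt == "binary_little_endian":
            data = np.frombuffer(fh.read(dtype.itemsize * n), dtype=dtype, count=n)
        else:
            raw = np.loadtxt(fh, max_rows=n, ndmin=2)
            data = np.empty(n, dtype=dtype)
            for i, (name, _) in enumerate(props):
                data[name] = raw[:, i]
    names = set(data.dtype.names)
    if not {"x", "y", "z"} <= names:
        raise ValueError("PLY vertex element lacks x/y/z")
    points = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    colors = None
    if {"red", "green", "blue"} <= names:
        colors = np.column_stack([data["red"], data["green"], data["blue"]]).astype(np.uint8)
    labels = data["label"].astype(np.uint8) if "label" in names else None
    consumed = {"x", "y", "z", "red", "green", "blue", "label"}
    attrs = {name: np.ascontiguousarray(data[name]) for name in data.dtype.names if name not in consumed}
    return PointCloud(points=points, colors=colors, labels=labels, attrs=attrs)
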