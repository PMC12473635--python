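"""Point-cloud plumbing: merge, voxel subsampling, NN difference binning, PLY I/O.

Coordinates are always millimetres. The PLY dialect written is binary little
endian with ``x,y,z`` as float32 and optional ``red,green,blue`` as uchar;
both ASCII and binary-little-endian files are read back.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "merge",
    "voxel_subsample",
    "nn_distance_bins",
    "read_ply",
    "write_ply",
    "PlyParseError",
]


class PlyParseError(ValueError):
    """Malformed PLY input; carries the offending header line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass
class PointCloud:
    """Points in rig coordinates (mm) with optional colors and provenance tags."""

    positions: np.ndarray
    colors: Optional[np.ndarray] = None
    tags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.positions):
                raise ValueError("colors must be one per point")
        if self.tags is not None:
            self.tags = np.asarray(self.tags)
            if len(self.tags) != len(self.positions):
                raise ValueError("tags must be one per point")

    def __len__(self) -> int:
        return len(self.positions)

    def select(self, mask_or_idx) -> "PointCloud":
        return PointCloud(
            positions=self.positions[mask_or_idx],
            colors=None if self.colors is None else self.colors[mask_or_idx],
            tags=None if self.tags is None else self.tags[mask_or_idx],
        )

    @staticmethod
    def empty() -> "PointCloud":
        return PointCloud(positions=np.zeros((0, 3)))


def merge(clouds: Sequence[PointCloud]) -> PointCloud:
    """Concatenate clouds, preserving colors/tags when all inputs carry them."""
    clouds = list(clouds)
    if not clouds:
        return PointCloud.empty()
    positions = np.concatenate([c.positions for c in clouds])
    colors = None
    if all(c.colors is not None for c in clouds) and len(positions):
        colors = np.concatenate([c.colors for c in clouds])
    tags = None
    if all(c.tags is not None for c in clouds) and len(positions):
        tags = np.concatenate([c.tags for c in clouds])
    return PointCloud(positions=positions, colors=colors, tags=tags)


def voxel_subsample(cloud: PointCloud, cell: float = 0.5) -> PointCloud:
    """One representative (member centroid) per occupied voxel.

    The grid is anchored at the coordinate origin so repeated runs with the
    same cell are reproducible; the centroid of a voxel's members stays inside
    the voxel, which makes the operation idempotent.
    """
    if cell <= 0:
        raise ValueError(f"cell must be positive, got {cell}")
    if len(cloud) == 0:
        return cloud
    keys = np.floor(cloud.positions / cell).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    n_vox = len(counts)
    centroids = np.zeros((n_vox, 3))
    np.add.at(centroids, inverse, cloud.positions)
    centroids /= counts[:, None]
    colors = None
    if cloud.colors is not None:
        acc = np.zeros((n_vox, 3))
        np.add.at(acc, inverse, cloud.colors.astype(float))
        colors = np.clip(np.round(acc / counts[:, None]), 0, 255).astype(np.uint8)
    tags = None
    if cloud.tags is not None:
        # first member's tag represents the voxel
        first = np.full(n_vox, -1, dtype=np.int64)
        order = np.arange(len(cloud))[::-1]
        first[inverse[order]] = order
        tags = cloud.tags[first]
    return PointCloud(positions=centroids, colors=colors, tags=tags)


def nn_distance_bins(
    cloud_a: PointCloud,
    cloud_b: PointCloud,
    edges: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 22.0),
) -> dict:
    """Histogram of nearest-neighbour distances from each point of A into B.

    Bins are half-open ``[e_i, e_{i+1})``; distances beyond the last edge go
    into ``overflow``. Also reports the below/above 3 mm split (again
    half-open: "below" means distance < 3 mm) used for cloud-difference
    summaries.
    """
    if len(cloud_b) == 0:
        raise ValueError("reference cloud B is empty")
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    d, _ = cKDTree(cloud_b.positions).query(cloud_a.positions, k=1)
    d = np.atleast_1d(d)
    idx = np.searchsorted(edges, d, side="right") - 1
    counts = [int(np.sum(idx == i)) for i in range(len(edges) - 1)]
    overflow = int(np.sum(d >= edges[-1]))
    below = int(np.sum(d < 3.0))
    return {
        "edges": edges.tolist(),
        "counts": counts,
        "overflow": overflow,
        "n": len(cloud_a),
        "below_3mm": below,
        "above_3mm": len(cloud_a) - below,
        "distances_max": float(d.max()) if len(d) else 0.0,
    }


_PLY_DTYPES = {
    "float": ("<f4", 4), "float32": ("<f4", 4),
    "double": ("<f8", 8), "float64": ("<f8", 8),
    "uchar": ("<u1", 1), "uint8": ("<u1", 1),
    "char": ("<i1", 1), "int8": ("<i1", 1),
    "ushort": ("<u2", 2), "uint16": ("<u2", 2),
    "short": ("<i2", 2), "int16": ("<i2", 2),
    "uint": ("<u4", 4), "uint32": ("<u4", 4),
    "int": ("<i4", 4), "int32": ("<i4", 4),
}


def write_ply(cloud: PointCloud, path) -> None:
    """Write a binary-little-endian PLY (x,y,z float32 mm; colors uchar)."""
    path = Path(path)
    has_color = cloud.colors is not None
    lines = [
        "ply",
        "format binary_little_endian 1.0",
        "comment generated by clcfm3",
        f"element vertex {len(cloud)}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if has_color:
        lines += ["property uchar red", "property uchar green", "property uchar blue"]
    lines.append("end_header")
    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    if has_color:
        fields += [("red", "<u1"), ("green", "<u1"), ("blue", "<u1")]
    rec = np.zeros(len(cloud), dtype=fields)
    pos32 = cloud.positions.astype("<f4")
    rec["x"], rec["y"], rec["z"] = pos32[:, 0], pos32[:, 1], pos32[:, 2]
    if has_color:
        rec["red"], rec["green"], rec["blue"] = (
            cloud.colors[:, 0], cloud.colors[:, 1], cloud.colors[:, 2],
        )
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


def read_ply(path) -> PointCloud:
    """Read a PLY point cloud (binary little endian or ASCII)."""
    path = Path(path)
    with open(path, "rb") as fh:
        data = fh.read()
    # header is ASCII terminated by end_header
    end = data.find(b"end_header")
    if end < 0:
        raise PlyParseError("missing end_header")
    header_bytes = data[: end + len(b"end_header")]
    try:
        header = header_bytes.decode("ascii").splitlines()
    except UnicodeDecodeError as exc:
        raise PlyParseError(f"non-ASCII header: {exc}") from exc
    if not header or header[0].strip() != "ply":
        raise PlyParseError("not a PLY file (missing 'ply' magic)", line=1)
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for ln, raw in enumerate(header[1:], start=2):
        tok = raw.strip().split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            if len(tok) < 2 or tok[1] not in ("ascii", "binary_little_endian"):
                raise PlyParseError(f"unsupported format {raw.strip()!r}", line=ln)
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                try:
                    n_vertex = int(tok[2])
                except (IndexError, ValueError):
                    raise PlyParseError("bad element vertex count", line=ln)
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise PlyParseError("list properties unsupported on vertices", line=ln)
            if tok[1] not in _PLY_DTYPES:
                raise PlyParseError(f"unknown property type {tok[1]!r}", line=ln)
            props.append((tok[2], _PLY_DTYPES[tok[1]][0]))
        elif tok[0] == "end_header":
            break
    if fmt is None or n_vertex is None:
        raise PlyParseError("header lacks format or vertex element")
    for need in ("x", "y", "z"):
        if need not in [p[0] for p in props]:
            raise PlyParseError(f"vertex element lacks property {need!r}")
    dtype = np.dtype([(name, dt) for name, dt in props])
    if fmt == "binary_little_endian":
        body = data[end + len(b"end_header") :]
        # skip the newline terminating the header
        nl = body.find(b"\n")
        body = body[nl + 1 :]
        if len(body) < n_vertex * dtype.itemsize:
            raise PlyParseError("truncated binary body")
        rec = np.frombuffer(body[: n_vertex * dtype.itemsize], dtype=dtype)
    else:
        text = data[end + len(b"end_header") :].decode("ascii").strip().splitlines()
        rows = [r.split() for r in text if r.strip()]
        if len(rows) < n_vertex:
            raise PlyParseError("truncated ASCII body")
        arr = np.array(rows[:n_vertex], dtype=float)
        rec = np.zeros(n_vertex, dtype=dtype)
        for i, (name, _) in enumerate(props):
            rec[name] = arr[:, i]
    positions = np.stack([rec["x"], rec["y"], rec["z"]], axis=1).astype(float)
    colors = None
    names = [p[0] for p in props]
    if all(c in names for c in ("red", "green", "blue")):
        colors = np.stack([rec["red"], rec["green"], rec["blue"]], axis=1).astype(np.uint8)
    return PointCloud(positions=positions, colors=colors)
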