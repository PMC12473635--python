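"""Synthetic turntable scenes: ground-truth plants, rig, and rendered inputs.

Emulates an all-around plant imaging studio: a potted plant (thin capsule
stems + planar elliptical leaves) standing on a rotating disc, three
random-dot pillars for feature stability, and coded targets at known
positions (disc centre, eight ring targets at 45-degree intervals 150 mm
from the centre, pillar targets stacked at 200 mm vertical spacing). A
fixed-step camera ring observes the scene; masks, depth maps and textured
images are produced by a CPU ray caster over the analytic primitives, so
every pipeline stage can be tested without photographs.

All randomness is driven by explicit seeds; there is no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cloud import PointCloud
from .geometry import (
    CameraIntrinsics,
    CameraPose,
    View,
    backproject,
    look_at,
    pixel_rays,
    project_points,
)

__all__ = [
    "Capsule",
    "EllipseDisc",
    "Box",
    "Sphere",
    "SceneModel",
    "RigSequence",
    "MaskImage",
    "DepthMap",
    "build_plant_scene",
    "build_turntable_rig",
    "render_mask",
    "render_depth",
    "render_texture_image",
    "sample_surface_points",
    "inject_flying_pixels",
    "DEFAULT_BACKGROUND_RGB",
]

DEFAULT_BACKGROUND_RGB = (20, 40, 225)  # the studio's blue back panel

_INVALID_DEPTH = np.inf


# ---------------------------------------------------------------------------
# Analytic primitives


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def intersect(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        oc = o - c
        b = np.sum(d * oc, axis=1)
        cterm = np.sum(oc * oc, axis=1) - self.radius**2
        disc = b * b - cterm
        hit = disc >= 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        t0 = -b - sq
        t1 = -b + sq
        t = np.where(t0 > 1e-9, t0, np.where(t1 > 1e-9, t1, _INVALID_DEPTH))
        return np.where(hit, t, _INVALID_DEPTH)

    def area(self) -> float:
        return 4.0 * math.pi * self.radius**2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return np.asarray(self.center) + self.radius * v


@dataclass(frozen=True)
class Capsule:
    """Segment p0->p1 swept by a sphere of the given radius (a stem)."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def _axis(self):
        p0 = np.asarray(self.p0, float)
        p1 = np.asarray(self.p1, float)
        ax = p1 - p0
        L = np.linalg.norm(ax)
        return p0, p1, ax / L, L

    def intersect(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        p0, p1, u, L = self._axis()
        r = self.radius
        oc = o - p0
        d_par = d @ u
        oc_par = oc @ u
        d_perp = d - d_par[:, None] * u
        oc_perp = oc - oc_par[:, None] * u
        a = np.sum(d_perp * d_perp, axis=1)
        b = np.sum(d_perp * oc_perp, axis=1)
        cterm = np.sum(oc_perp * oc_perp, axis=1) - r * r
        disc = b * b - a * cterm
        t_cyl = np.full(len(o), _INVALID_DEPTH)
        ok = (disc >= 0) & (a > 1e-15)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        for sgn in (-1.0, 1.0):
            t = np.where(ok, (-b + sgn * sq) / np.where(a > 1e-15, a, 1.0), _INVALID_DEPTH)
            s = oc_par + t * d_par  # axial coordinate of the hit
            good = ok & (t > 1e-9) & (s >= 0) & (s <= L)
            t_cyl = np.where(good & (t < t_cyl), t, t_cyl)
        t0 = Sphere(tuple(p0), r).intersect(o, d)
        t1 = Sphere(tuple(p1), r).intersect(o, d)
        return np.minimum(t_cyl, np.minimum(t0, t1))

    def area(self) -> float:
        _, _, _, L = self._axis()
        return 2 * math.pi * self.radius * L + 4 * math.pi * self.radius**2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p0, p1, u, L = self._axis()
        side = 2 * math.pi * self.radius * L
        caps = 4 * math.pi * self.radius**2
        pick_side = rng.random(n) < side / (side + caps)
        # orthonormal frame around the axis
        tmp = np.array([1.0, 0.0, 0.0])
        if abs(u @ tmp) > 0.9:
            tmp = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, tmp)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        out = np.empty((n, 3))
        th = rng.uniform(0, 2 * math.pi, n)
        s = rng.uniform(0, L, n)
        ring = self.radius * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)
        out[pick_side] = p0 + s[pick_side, None] * u + ring[pick_side]
        m = ~pick_side
        v = rng.normal(size=(int(m.sum()), 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        top = v @ u > 0
        ends = np.where(top[:, None], p1, p0)
        out[m] = ends + self.radius * v
        return out


@dataclass(frozen=True)
class EllipseDisc:
    """A planar, two-sided ellipse (a leaf blade)."""

    center: tuple[float, float, float]
    normal: tuple[float, float, float]
    major_dir: tuple[float, float, float]
    semi_a: float
    semi_b: float

    def _frame(self):
        c = np.asarray(self.center, float)
        n = np.asarray(self.normal, float)
        n = n / np.linalg.norm(n)
        u = np.asarray(self.major_dir, float)
        u = u - (u @ n) * n
        u = u / np.linalg.norm(u)
        v = np.cross(n, u)
        return c, n, u, v

    def intersect(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        c, n, u, v = self._frame()
        denom = d @ n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((c - o) @ n) / denom
        p = o + t[:, None] * d
        a = (p - c) @ u
        b = (p - c) @ v
        inside = (a / self.semi_a) ** 2 + (b / self.semi_b) ** 2 <= 1.0
        good = (np.abs(denom) > 1e-12) & (t > 1e-9) & inside
        return np.where(good, t, _INVALID_DEPTH)

    def area(self) -> float:
        return math.pi * self.semi_a * self.semi_b

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        c, _, u, v = self._frame()
        r = np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * math.pi, n)
        return (
            c
            + (r * np.cos(th) * self.semi_a)[:, None] * u
            + (r * np.sin(th) * self.semi_b)[:, None] * v
        )


@dataclass(frozen=True)
class Box:
    """Oriented box; rotation rows are the box axes in world coordinates."""

    center: tuple[float, float, float]
    half_sizes: tuple[float, float, float]
    rotation: tuple = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

    def intersect(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        R = np.asarray(self.rotation, float)
        h = np.asarray(self.half_sizes, float)
        ol = (o - np.asarray(self.center)) @ R.T
        dl = d @ R.T
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / dl
        t1 = (-h - ol) * inv
        t2 = (h - ol) * inv
        # where the ray is parallel to a slab, fall back to +-inf bounds
        par = np.abs(dl) < 1e-15
        lo = np.where(par, np.where(np.abs(ol) <= h, -np.inf, np.inf), np.minimum(t1, t2))
        hi = np.where(par, np.where(np.abs(ol) <= h, np.inf, -np.inf), np.maximum(t1, t2))
        tmin = lo.max(axis=1)
        tmax = hi.min(axis=1)
        hit = (tmax >= tmin) & (tmax > 1e-9)
        t = np.where(tmin > 1e-9, tmin, tmax)
        return np.where(hit, t, _INVALID_DEPTH)

    def area(self) -> float:
        a, b, c = self.half_sizes
        return 8.0 * (a * b + b * c + a * c)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        R = np.asarray(self.rotation, float)
        h = np.asarray(self.half_sizes, float)
        areas = np.array([h[1] * h[2], h[0] * h[2], h[0] * h[1]], float)
        face_axis = rng.choice(3, size=n, p=areas / areas.sum())
        sign = rng.choice([-1.0, 1.0], size=n)
        p = rng.uniform(-1, 1, size=(n, 3)) * h
        p[np.arange(n), face_axis] = sign * h[face_axis]
        return np.asarray(self.center) + p @ R


# ---------------------------------------------------------------------------
# Scene and rig containers


@dataclass
class MaskImage:
    """Binary silhouette aligned to a view: foreground = 1, background = 0."""

    values: np.ndarray  # (H, W) uint8 in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.values = self.values.astype(np.uint8)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class DepthMap:
    """Per-pixel distance along the camera ray (mm); inf marks background."""

    values: np.ndarray  # (H, W) float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class SceneModel:
    """Ground truth: plant primitives, disc, pillars, coded-target positions."""

    plant: list
    structures: list  # disc + pillars (non-plant geometry)
    coded_targets: list[tuple[int, np.ndarray]]
    rng_seed: int = 0
    bounding_radius: float = 800.0
    bounding_height: float = 1400.0

    def __post_init__(self) -> None:
        ids = [tid for tid, _ in self.coded_targets]
        if len(ids) != len(set(ids)):
            raise ValueError("coded-target IDs must be unique")
        self.coded_targets = [(int(t), np.asarray(p, float).reshape(3)) for t, p in self.coded_targets]

    def primitives(self, foreground: str = "plant") -> list:
        if foreground == "plant":
            return list(self.plant)
        if foreground == "plant+structure":
            return list(self.plant) + list(self.structures)
        if foreground == "all":
            return list(self.plant) + list(self.structures)
        raise ValueError(f"unknown foreground set {foreground!r}")

    def target_positions(self) -> dict[int, np.ndarray]:
        return {tid: pos for tid, pos in self.coded_targets}


@dataclass
class RigSequence:
    """The ordered ring of views plus ground-truth poses."""

    views: list[View]
    n_rotations: int
    step_deg: float
    camera_rows: int
    gt_poses: dict[str, CameraPose]

    def __post_init__(self) -> None:
        if len(self.views) != self.n_rotations * self.camera_rows:
            raise ValueError("views must number n_rotations * camera_rows")
        if abs(self.step_deg * self.n_rotations - 360.0) > 1e-9:
            raise ValueError("step_deg * n_rotations must equal 360")

    def row(self, camera_row: int) -> list[View]:
        return [v for v in self.views if v.camera_row == camera_row]

    def with_estimated_poses(self, poses: dict[str, CameraPose]) -> "RigSequence":
        views = [v.with_pose(poses[v.view_id]) if v.view_id in poses else v for v in self.views]
        return RigSequence(views, self.n_rotations, self.step_deg, self.camera_rows, self.gt_poses)

    def gt_view(self, view: View) -> View:
        return view.with_pose(self.gt_poses[view.view_id])


# ---------------------------------------------------------------------------
# Builders


def build_plant_scene(
    n_stems: int = 3,
    stem_height: float = 350.0,
    stem_radius: float = 2.5,
    n_leaves: int = 6,
    leaf_semi_a: float = 45.0,
    leaf_semi_b: float = 28.0,
    seed: int = 0,
    disc_radius: float = 175.0,
    pillar_distance: float = 230.0,
    pillar_height: float = 1000.0,
    ring_target_radius: float = 150.0,
    pillar_target_spacing: float = 200.0,
) -> SceneModel:
    """Deterministic parametric plant on a disc with pillars and coded targets.

    The target layout follows the studio convention: one target at the disc
    centre, eight on a ring of ``ring_target_radius`` at 45-degree intervals,
    and targets stacked every ``pillar_target_spacing`` mm up each pillar.
    """
    if stem_radius <= 0 or leaf_semi_a <= 0 or leaf_semi_b <= 0 or stem_height <= 0:
        raise ValueError("primitive sizes must be positive")
    if n_stems < 0 or n_leaves < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)

    plant: list = []
    stem_tops = []
    for _ in range(n_stems):
        base = np.array([rng.uniform(-30, 30), rng.uniform(-30, 30), 0.0])
        lean = rng.uniform(-0.12, 0.12, size=2)
        h = stem_height * rng.uniform(0.7, 1.0)
        top = base + np.array([lean[0] * h, lean[1] * h, h])
        plant.append(Capsule(tuple(base), tuple(top), stem_radius))
        stem_tops.append((base, top))
    for _ in range(n_leaves):
        if stem_tops:
            base, top = stem_tops[rng.integers(len(stem_tops))]
            s = rng.uniform(0.4, 1.0)
            anchor = base + s * (top - base)
        else:
            anchor = np.array([0.0, 0.0, stem_height * 0.5])
        az = rng.uniform(0, 2 * math.pi)
        out = np.array([math.cos(az), math.sin(az), 0.0])
        center = anchor + out * (leaf_semi_a * rng.uniform(0.8, 1.4))
        tilt = rng.uniform(-0.5, 0.5)
        normal = np.array([-math.sin(tilt) * math.cos(az), -math.sin(tilt) * math.sin(az), math.cos(tilt)])
        plant.append(
            EllipseDisc(
                tuple(center),
                tuple(normal),
                tuple(out),
                leaf_semi_a * rng.uniform(0.8, 1.2),
                leaf_semi_b * rng.uniform(0.8, 1.2),
            )
        )

    structures: list = [
        EllipseDisc((0.0, 0.0, 0.0), (0.0, 0.0, 1.0), (1.0, 0.0, 0.0), disc_radius, disc_radius)
    ]
    targets: list[tuple[int, np.ndarray]] = [(0, np.zeros(3))]
    for k in range(8):
        a = math.radians(45.0 * k)
        targets.append(
            (k + 1, np.array([ring_target_radius * math.cos(a), ring_target_radius * math.sin(a), 0.0]))
        )
    pillar_angles = [90.0, 210.0, 330.0]
    for j, ang in enumerate(pillar_angles):
        a = math.radians(ang)
        direction = np.array([math.cos(a), math.sin(a), 0.0])
        center = direction * pillar_distance + np.array([0.0, 0.0, pillar_height / 2])
        # box axes: radial (thickness), tangential (width), vertical (length)
        tang = np.array([-math.sin(a), math.cos(a), 0.0])
        R = (tuple(direction), tuple(tang), (0.0, 0.0, 1.0))
        structures.append(Box(tuple(center), (7.5, 12.5, pillar_height / 2), R))
        n_t = int(pillar_height // pillar_target_spacing)
        for i in range(1, n_t + 1):
            z = i * pillar_target_spacing
            pos = direction * (pillar_distance - 7.5) + np.array([0.0, 0.0, z])
            targets.append((100 * (j + 1) + i, pos))

    return SceneModel(
        plant=plant,
        structures=structures,
        coded_targets=targets,
        rng_seed=seed,
        bounding_radius=pillar_distance + 50.0,
        bounding_height=pillar_height + 100.0,
    )


def build_turntable_rig(
    n_rotations: int = 72,
    step_deg: float = 5.0,
    camera_rows: int = 4,
    heights: Optional[Sequence[float]] = None,
    distance: float = 1500.0,
    image_size: tuple[int, int] = (320, 240),
    focal_px: float = 320.0,
    target_height_range: tuple[float, float] = (400.0, 1200.0),
) -> RigSequence:
    """Ground-truth camera ring for a turntable of ``n_rotations`` stops.

    Rotating the object by +theta is represented as a camera at azimuth
    -theta about the turntable axis; each view's ``azimuth_deg`` records the
    stage rotation ``rotation_index * step_deg``. Camera heights default to an
    even spread over the accommodated plant-height range and every camera
    aims at the centre of that plant volume.
    """
    if abs(n_rotations * step_deg - 360.0) > 1e-9:
        raise ValueError("n_rotations * step_deg must equal 360")
    lo, hi = target_height_range
    if heights is None:
        if camera_rows == 1:
            heights = [0.55 * hi]
        else:
            heights = list(np.linspace(0.3 * hi, 1.1 * hi, camera_rows))
    if len(heights) != camera_rows:
        raise ValueError("one height per camera row required")
    aim = np.array([0.0, 0.0, 0.5 * hi])
    intr = CameraIntrinsics(
        focal_px=focal_px,
        principal_point=((image_size[0] - 1) / 2.0, (image_size[1] - 1) / 2.0),
        image_size=image_size,
    )
    views: list[View] = []
    gt: dict[str, CameraPose] = {}
    for row in range(camera_rows):
        for r in range(n_rotations):
            az = (r * step_deg) % 360.0
            phi = math.radians(-az)
            center = np.array([distance * math.cos(phi), distance * math.sin(phi), heights[row]])
            pose = look_at(center, aim)
            vid = f"r{row}_i{r:03d}"
            views.append(
                View(
                    view_id=vid,
                    camera_row=row,
                    rotation_index=r,
                    azimuth_deg=az,
                    intrinsics=intr,
                    pose=pose,
                )
            )
            gt[vid] = pose
    return RigSequence(views=views, n_rotations=n_rotations, step_deg=step_deg, camera_rows=camera_rows, gt_poses=gt)


# ---------------------------------------------------------------------------
# Rendering


def _cast(primitives: list, o: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest-hit distance and primitive index (-1 = miss) per ray."""
    t_best = np.full(len(d), _INVALID_DEPTH)
    idx = np.full(len(d), -1, dtype=np.int64)
    for i, prim in enumerate(primitives):
        t = prim.intersect(o, d)
        closer = t < t_best
        t_best = np.where(closer, t, t_best)
        idx = np.where(closer, i, idx)
    return t_best, idx


def _view_rays(view: View) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    w, h = view.intrinsics.image_size
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    uv = np.stack([uu.ravel(), vv.ravel()], axis=1)
    origin, dirs = pixel_rays(view, uv)
    return np.broadcast_to(origin, dirs.shape), dirs, (h, w)


def render_depth(scene: SceneModel, view: View, foreground: str = "plant") -> DepthMap:
    """Ray-cast depth (distance along the ray, mm) for the foreground set."""
    o, d, shape = _view_rays(view)
    prims = scene.primitives(foreground)
    if not prims:
        return DepthMap(values=np.full(shape, _INVALID_DEPTH))
    t, _ = _cast(prims, o, d)
    return DepthMap(values=t.reshape(shape))


def render_mask(scene: SceneModel, view: View, foreground: str = "plant") -> MaskImage:
    """Silhouette of the foreground set (plant-only by default, for carving)."""
    depth = render_depth(scene, view, foreground)
    return MaskImage(values=depth.valid.astype(np.uint8))


def _hash01(cells: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic per-cell pseudo-random values in [0, 1)."""
    x = cells.astype(np.uint64)
    h = (
        x[:, 0] * np.uint64(73856093)
        ^ x[:, 1] * np.uint64(19349663)
        ^ x[:, 2] * np.uint64(83492791)
        ^ np.uint64(seed & 0x7FFFFFFF) * np.uint64(2654435761)
    )
    h ^= h >> np.uint64(13)
    h = h * np.uint64(0x9E3779B97F4A7C15)
    h ^= h >> np.uint64(31)
    return (h & np.uint64(0xFFFFFF)).astype(float) / float(0x1000000)


def render_texture_image(
    scene: SceneModel,
    view: View,
    seed: int = 0,
    background_rgb: tuple[int, int, int] = DEFAULT_BACKGROUND_RGB,
    dot_size_mm: float = 6.0,
) -> np.ndarray:
    """Textured RGB rendering: blue background, random-dot surfaces, targets.

    The dot texture is a deterministic hash of the 3D hit position quantised
    at ``dot_size_mm``, so the same surface patch shows the same dots from
    every viewpoint — a stable signal for feature matching, standing in for
    the printed random-dot strips of the physical stage.
    """
    o, d, shape = _view_rays(view)
    plant = list(scene.plant)
    prims = plant + list(scene.structures)
    img = np.empty((shape[0] * shape[1], 3), dtype=np.uint8)
    img[:] = np.asarray(background_rgb, dtype=np.uint8)
    if prims:
        t, idx = _cast(prims, o, d)
        hit = np.isfinite(t)
        if hit.any():
            p = o[hit] + t[hit, None] * d[hit]
            cells = np.floor(p / dot_size_mm).astype(np.int64)
            rnd = _hash01(cells, seed)
            base = np.where(
                (idx[hit] < len(plant))[:, None],
                np.array([60, 150, 60], dtype=float),
                np.array([170, 170, 170], dtype=float),
            )
            shade = np.where(rnd < 0.5, 0.35, 1.0)
            img[hit] = np.clip(base * shade[:, None], 0, 255).astype(np.uint8)
    img = img.reshape(shape[0], shape[1], 3)

    # coded targets: concentric high-contrast rings splatted at the projection
    depth_all = None
    positions = scene.target_positions()
    if positions:
        t_all, _ = _cast(prims, o, d) if prims else (np.full(len(d), _INVALID_DEPTH), None)
        depth_all = t_all.reshape(shape)
        h, w = shape
        cam = view.pose.center
        for tid, pos in positions.items():
            uvs, ok = project_points(pos[None, :], view)
            if not ok[0]:
                continue
            u, v = uvs[0]
            if not (0 <= u < w and 0 <= v < h):
                continue
            dist = np.linalg.norm(pos - cam)
            if depth_all[int(round(v)), int(round(u))] < dist - 15.0:
                continue  # occluded
            rad = 5
            u0, v0 = int(round(u)), int(round(v))
            for dv in range(-rad, rad + 1):
                for du in range(-rad, rad + 1):
                    uu, vv = u0 + du, v0 + dv
                    if not (0 <= uu < w and 0 <= vv < h):
                        continue
                    rr = math.hypot(du, dv)
                    if rr > rad:
                        continue
                    ring = int(rr) + tid
                    img[vv, uu] = 255 if ring % 2 == 0 else 0
    return img


def sample_surface_points(scene: SceneModel, n: int, seed: int = 0) -> PointCloud:
    """Uniform-area samples on the plant surface (ground-truth oracle)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not scene.plant:
        raise ValueError("scene has no plant primitives to sample")
    rng = np.random.default_rng(seed)
    areas = np.array([p.area() for p in scene.plant], float)
    counts = rng.multinomial(n, areas / areas.sum())
    parts = [p.sample(int(k), rng) for p, k in zip(scene.plant, counts) if k > 0]
    pts = np.concatenate(parts) if parts else np.zeros((0, 3))
    return PointCloud(positions=pts, tags=np.array(["surface"] * len(pts)))


def boundary_pixels(mask: MaskImage) -> np.ndarray:
    """Foreground pixels with at least one 4-connected background neighbour."""
    m = mask.values.astype(bool)
    er = np.zeros_like(m)
    er[1:-1, 1:-1] = m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    edge = m & ~er
    vv, uu = np.nonzero(edge)
    return np.stack([uu, vv], axis=1)


def inject_flying_pixels(
    cloud: PointCloud,
    scene: SceneModel,
    views: Sequence[View],
    n: int,
    depth_perturbation: float = 20.0,
    seed: int = 0,
) -> PointCloud:
    """Add stereo-mismatch noise points at silhouette boundaries.

    Emulates flying pixels: at an object boundary the stereo correspondence
    can lock onto background texture, shifting the ray depth DP; the
    reconstructed point then leaves the surface along the viewing ray. Each
    injected point keeps a boundary pixel's ray and perturbs its depth by
    +-``depth_perturbation``; injected points are tagged ``"flying"``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return cloud
    rng = np.random.default_rng(seed)
    per_view: list[tuple[View, np.ndarray, DepthMap]] = []
    for view in views:
        mask = render_mask(scene, view, foreground="plant")
        edge = boundary_pixels(mask)
        if len(edge):
            per_view.append((view, edge, render_depth(scene, view, foreground="plant")))
    if not per_view:
        raise ValueError("no silhouette boundary pixels in any view")
    new_pts = np.empty((n, 3))
    for i in range(n):
        view, edge, depth = per_view[rng.integers(len(per_view))]
        u, v = edge[rng.integers(len(edge))]
        dp = depth.values[v, u]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        new_pts[i] = backproject(view, np.array([[float(u), float(v)]]), dp + sign * depth_perturbation)[0]
    injected = PointCloud(positions=new_pts, tags=np.array(["flying"] * n))
    base_tags = cloud.tags if cloud.tags is not None else np.array(["orig"] * len(cloud))
    return PointCloud(
        positions=np.concatenate([cloud.positions, injected.positions]),
        colors=None,
        tags=np.concatenate([base_tags, injected.tags]),
    )
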