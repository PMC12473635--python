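"""Feature front-ends for camera alignment.

The scheduler and bundle adjustment consume abstract feature *tracks*
(track_id -> {view_id -> pixel}), produced by one of two interchangeable
front-ends:

* :class:`OracleFrontEnd` — projects known synthetic 3D feature points with
  the ground-truth poses and optional Gaussian pixel noise. This isolates
  the alignment machinery from detector quality and is the reference path
  for tests and simulation studies.
* :class:`ImageFrontEnd` — Harris corners matched by ZNCC patch correlation
  with a ratio test, linked into tracks across neighbouring rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import corner_harris, corner_peaks

from .geometry import View, project_points
from .synthetic import RigSequence, SceneModel, sample_surface_points

__all__ = ["TrackSet", "OracleFrontEnd", "ImageFrontEnd", "detect_corners"]


@dataclass
class TrackSet:
    """Feature tracks: per-track pixel observations keyed by view id."""

    obs: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    def add(self, track_id: int, view_id: str, uv) -> None:
        self.obs.setdefault(track_id, {})[view_id] = np.asarray(uv, float)

    def tracks_seen_by(self, view_id: str) -> list[int]:
        return [t for t, per in self.obs.items() if view_id in per]

    def shared(self, vid_a: str, vid_b: str) -> list[int]:
        return [t for t, per in self.obs.items() if vid_a in per and vid_b in per]

    def n_tracks(self) -> int:
        return len(self.obs)


class OracleFrontEnd:
    """Tracks from known 3D feature points projected with ground-truth poses.

    Feature points are drawn from the plant surface, the pillar/disc
    structure and the coded targets; observations get i.i.d. Gaussian pixel
    noise of ``noise_sigma_px``. The scene is treated as transparent: a point
    is observed wherever its projection is in front of the camera and inside
    the image.
    """

    def __init__(
        self,
        scene: SceneModel,
        rig: RigSequence,
        n_points: int = 260,
        noise_sigma_px: float = 0.0,
        seed: int = 0,
        mask_filter: Optional[Callable[[str, np.ndarray], np.ndarray]] = None,
    ):
        self.scene = scene
        self.rig = rig
        self.noise_sigma_px = noise_sigma_px
        self.seed = seed
        self.mask_filter = mask_filter
        rng = np.random.default_rng(seed)
        pts = []
        if scene.plant:
            n_plant = max(1, n_points // 2)
            pts.append(sample_surface_points(scene, n_plant, seed=int(rng.integers(2**31 - 1))).positions)
        n_struct = n_points - sum(len(p) for p in pts)
        if scene.structures and n_struct > 0:
            areas = np.array([p.area() for p in scene.structures])
            counts = rng.multinomial(n_struct, areas / areas.sum())
            for prim, k in zip(scene.structures, counts):
                if k > 0:
                    pts.append(prim.sample(int(k), rng))
        if scene.coded_targets:
            pts.append(np.stack([pos for _, pos in scene.coded_targets]))
        self.points3d = np.concatenate(pts) if pts else np.zeros((0, 3))

    def build_tracks(self, views: Sequence[View]) -> TrackSet:
        rng = np.random.default_rng(self.seed + 1)
        tracks = TrackSet()
        w, h = views[0].intrinsics.image_size
        for view in views:
            gt = self.rig.gt_view(view)
            uv, in_front = project_points(self.points3d, gt)
            if self.noise_sigma_px > 0:
                uv = uv + rng.normal(0.0, self.noise_sigma_px, size=uv.shape)
            ok = in_front & (uv[:, 0] >= 0) & (uv[:, 0] < w) & (uv[:, 1] >= 0) & (uv[:, 1] < h)
            if self.mask_filter is not None:
                ok = ok & self.mask_filter(view.view_id, uv)
            for tid in np.nonzero(ok)[0]:
                tracks.add(int(tid), view.view_id, uv[tid])
        return tracks


def detect_corners(image: np.ndarray, max_corners: int = 600) -> np.ndarray:
    """Harris corner positions (u, v) in an RGB or grayscale image."""
    gray = rgb2gray(image) if image.ndim == 3 else image.astype(float)
    resp = corner_harris(gray, sigma=1.2)
    peaks = corner_peaks(resp, min_distance=4, num_peaks=max_corners)
    return peaks[:, ::-1].astype(float)  # (row, col) -> (u, v)


def _patches(gray: np.ndarray, uv: np.ndarray, half: int = 5) -> tuple[np.ndarray, np.ndarray]:
    h, w = gray.shape
    keep = (
        (uv[:, 0] >= half) & (uv[:, 0] < w - half) & (uv[:, 1] >= half) & (uv[:, 1] < h - half)
    )
    uv = uv[keep]
    out = np.empty((len(uv), (2 * half + 1) ** 2))
    for i, (u, v) in enumerate(uv.astype(int)):
        p = gray[v - half : v + half + 1, u - half : u + half + 1].ravel()
        p = p - p.mean()
        n = np.linalg.norm(p)
        out[i] = p / n if n > 1e-9 else p
    return uv, out


class ImageFrontEnd:
    """Corner detection + ZNCC patch matching between nearby rotations."""

    def __init__(
        self,
        image_provider: Callable[[View], np.ndarray],
        max_corners: int = 600,
        ratio: float = 0.9,
        zncc_min: float = 0.7,
        link_window: int = 2,
    ):
        self.image_provider = image_provider
        self.max_corners = max_corners
        self.ratio = ratio
        self.zncc_min = zncc_min
        self.link_window = link_window

    def build_tracks(self, views: Sequence[View]) -> TrackSet:
        feats = {}
        for view in views:
            img = self.image_provider(view)
            gray = rgb2gray(img) if img.ndim == 3 else img.astype(float)
            uv = detect_corners(img, self.max_corners)
            feats[view.view_id] = _patches(gray, uv)
        # union-find over (view, feature) nodes
        parent: dict[tuple[str, int], tuple[str, int]] = {}

        def find(x):
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        ordered = sorted(views, key=lambda v: (v.camera_row, v.rotation_index))
        n_rot = max(v.rotation_index for v in views) + 1
        for i, va in enumerate(ordered):
            for vb in ordered[i + 1 :]:
                same_row = va.camera_row == vb.camera_row
                dr = min(
                    abs(va.rotation_index - vb.rotation_index),
                    n_rot - abs(va.rotation_index - vb.rotation_index),
                )
                if not (dr <= self.link_window or (dr == 0 and not same_row)):
                    continue
                uva, da = feats[va.view_id]
                uvb, db = feats[vb.view_id]
                if len(uva) == 0 or len(uvb) == 0:
                    continue
                sim = da @ db.T
                best = np.argmax(sim, axis=1)
                smax = sim[np.arange(len(uva)), best]
                sim_no_best = sim.copy()
                sim_no_best[np.arange(len(uva)), best] = -np.inf
                second = sim_no_best.max(axis=1)
                back = np.argmax(sim, axis=0)
                for ia, ib in enumerate(best):
                    if smax[ia] < self.zncc_min:
                        continue
                    if second[ia] > self.ratio * smax[ia]:
                        continue
                    if back[ib] != ia:
                        continue
                    union((va.view_id, ia), (vb.view_id, ib))
        groups: dict[tuple[str, int], list[tuple[str, int]]] = {}
        for node in list(parent):
            groups.setdefault(find(node), []).append(node)
        tracks = TrackSet()
        tid = 0
        for members in groups.values():
            per_view = {}
            for vid, ifeat in members:
                if vid in per_view:
                    break  # inconsistent track; drop
                per_view[vid] = feats[vid][0][ifeat]
            else:
                if len(per_view) >= 2:
                    for vid, uv in per_view.items():
                        tracks.add(tid, vid, uv)
                    tid += 1
        return tracks
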