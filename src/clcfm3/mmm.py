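"""Multi-masked matching (MMM) densification.

Dense reconstruction here is deliberately local: every pair of adjacent
camera positions on a row builds its own narrow-baseline point cloud (the
*baseCloud*), which keeps occlusion holes small on thin plant structures
(multi-matching). Narrow baselines, however, breed flying pixels — stereo
mismatches at silhouette boundaries that scatter points off the surface
along the viewing ray. Those are carved away by projecting every baseCloud
point into the silhouette masks of all views within an angular fan around
the pair (default 90 degrees: 45 to each side) and deleting points that
land on background in any of them (masked matching). Wider fans remove
more noise but also start carving true plant points seen obliquely, so the
fan angle is the noise/defect trade-off knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
from scipy.ndimage import binary_dilation

from .cloud import PointCloud
from .geometry import View, backproject, project_points
from .synthetic import DepthMap, MaskImage, RigSequence, SceneModel, render_depth

__all__ = [
    "PairJob",
    "DepthSource",
    "OracleDepthSource",
    "BlockMatchingDepthSource",
    "enumerate_pairs",
    "stereo_basecloud",
    "select_mask_fan",
    "remove_masked_points",
    "mmm_run",
]


@dataclass
class PairJob:
    """One adjacent-rotation stereo job on a single camera row."""

    camera_row: int
    rotations: tuple[int, int]
    view_a: View
    view_b: View
    mean_azimuth_deg: float

    @property
    def tag(self) -> str:
        return f"row{self.camera_row}_pair{self.rotations[0]:03d}-{self.rotations[1]:03d}"


class DepthSource(Protocol):
    """Contract: dense ray-depth for a pair's reference view."""

    def depth_for_pair(self, pair: PairJob, masks) -> DepthMap: ...


class OracleDepthSource:
    """Ground-truth depth from the synthetic renderer (ray-cast)."""

    def __init__(self, scene: SceneModel, rig: RigSequence, foreground: str = "plant"):
        self.scene = scene
        self.rig = rig
        self.foreground = foreground

    def depth_for_pair(self, pair: PairJob, masks=None) -> DepthMap:
        # depth is rendered with the ground-truth pose: it stands in for a
        # perfect matcher, while the carving still runs on estimated poses
        return render_depth(self.scene, self.rig.gt_view(pair.view_a), self.foreground)


class BlockMatchingDepthSource:
    """Rectified ZNCC block matching on rendered or loaded images."""

    def __init__(
        self,
        image_provider: Callable[[View], np.ndarray],
        depth_range: tuple[float, float] = (300.0, 3000.0),
        window: int = 7,
        zncc_min: float = 0.3,
    ):
        self.image_provider = image_provider
        self.depth_range = depth_range
        self.window = window
        self.zncc_min = zncc_min

    def depth_for_pair(self, pair: PairJob, masks=None) -> DepthMap:
        from .stereo import block_matching_depth

        return block_matching_depth(
            pair.view_a,
            pair.view_b,
            self.image_provider(pair.view_a),
            self.image_provider(pair.view_b),
            depth_range=self.depth_range,
            window=self.window,
            zncc_min=self.zncc_min,
        )


def _circular_diff_deg(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def enumerate_pairs(rig: RigSequence) -> list[PairJob]:
    """All adjacent-rotation pairs per camera row, including the wrap-around.

    One job per (row, rotation): with n rotations the pairs are (0,1) ...
    (n-2, n-1), (n-1, 0), so a rig of R rows yields R * n jobs.
    """
    if rig.n_rotations < 2:
        raise ValueError("need at least two rotations for adjacency")
    for v in rig.views:
        if v.pose is None:
            raise ValueError(f"view {v.view_id} is not aligned (no pose)")
    jobs: list[PairJob] = []
    for row in range(rig.camera_rows):
        row_views = sorted(rig.row(row), key=lambda v: v.rotation_index)
        n = rig.n_rotations
        for r in range(n):
            va = row_views[r]
            vb = row_views[(r + 1) % n]
            az_a, az_b = va.azimuth_deg, vb.azimuth_deg
            # circular mean of two adjacent stops
            mean = (az_a + _circular_diff_deg(az_a, az_b) / 2.0) % 360.0
            jobs.append(
                PairJob(
                    camera_row=row,
                    rotations=(va.rotation_index, vb.rotation_index),
                    view_a=va,
                    view_b=vb,
                    mean_azimuth_deg=mean,
                )
            )
    return jobs


def _get_mask(masks, view: View) -> MaskImage:
    try:
        m = masks(view.view_id) if callable(masks) else masks[view.view_id]
    except KeyError as exc:
        raise FileNotFoundError(f"mask missing for view {view.view_id}") from exc
    return m


def stereo_basecloud(
    pair: PairJob,
    depth_source: DepthSource,
    masks,
    image_provider: Optional[Callable[[View], np.ndarray]] = None,
) -> PointCloud:
    """Backproject the pair's depth map into a tagged local point cloud.

    Every reference pixel with valid depth and foreground mask becomes a 3D
    point at distance DP along its viewing ray; colors are sampled from the
    reference image when available, and all points carry the pair tag.
    """
    depth = depth_source.depth_for_pair(pair, masks)
    mask = _get_mask(masks, pair.view_a)
    valid = depth.valid & (mask.values > 0)
    vv, uu = np.nonzero(valid)
    if len(uu) == 0:
        return PointCloud(positions=np.zeros((0, 3)), tags=np.array([], dtype=object))
    uv = np.stack([uu.astype(float), vv.astype(float)], axis=1)
    pts = backproject(pair.view_a, uv, depth.values[vv, uu])
    colors = None
    if image_provider is not None:
        img = image_provider(pair.view_a)
        colors = img[vv, uu].astype(np.uint8)
    return PointCloud(positions=pts, colors=colors, tags=np.array([pair.tag] * len(pts)))


def select_mask_fan(pair: PairJob, rig: RigSequence, fan_deg: float = 90.0) -> list[View]:
    """Views whose azimuth lies within fan_deg/2 of the pair's mean azimuth.

    All camera rows participate; with a 72 x 5-degree ring, 4 rows and the
    default 90-degree fan this selects 72 mask images (18 rotation stops x 4
    rows), the pair's own views included.
    """
    if not (0.0 <= fan_deg <= 360.0):
        raise ValueError("fan_deg must be in [0, 360]")
    half = fan_deg / 2.0
    return [
        v for v in rig.views if _circular_diff_deg(v.azimuth_deg, pair.mean_azimuth_deg) <= half
    ]


def remove_masked_points(
    cloud: PointCloud,
    fan_views: Sequence[View],
    masks,
    min_bg_views: int = 1,
    dilate_radius: int = 0,
) -> PointCloud:
    """Carve points that project onto background in the fan's masks.

    A fan view votes to remove a point iff the point is in front of that
    camera, its projection falls inside the image, and the nearest mask
    pixel is background; out-of-bounds and behind-camera projections
    abstain. A point is removed when at least ``min_bg_views`` views vote
    (default 1: any single background view suffices, the visual-hull
    semantics). ``dilate_radius`` > 0 grows the foreground before lookup to
    protect true boundary points from mask erosion.
    """
    if len(cloud) == 0:
        return cloud
    votes = np.zeros(len(cloud), dtype=np.int64)
    for view in fan_views:
        mask = _get_mask(masks, view)
        m = mask.values
        if dilate_radius > 0:
            m = binary_dilation(m, iterations=dilate_radius).astype(np.uint8)
        h, w = m.shape
        uv, in_front = project_points(cloud.positions, view)
        ui = np.round(uv[:, 0]).astype(int)
        vi = np.round(uv[:, 1]).astype(int)
        in_bounds = (ui >= 0) & (ui < w) & (vi >= 0) & (vi < h)
        eligible = in_front & in_bounds
        bg = np.zeros(len(cloud), dtype=bool)
        idx = np.nonzero(eligible)[0]
        bg[idx] = m[vi[idx], ui[idx]] == 0
        votes += bg
    keep = votes < min_bg_views
    return cloud.select(keep)


def mmm_run(
    rig: RigSequence,
    depth_source: DepthSource,
    masks,
    fan_deg: float = 90.0,
    min_bg_views: int = 1,
    image_provider: Optional[Callable[[View], np.ndarray]] = None,
    log: Optional[list] = None,
) -> list[PointCloud]:
    """Build and carve one baseCloud per adjacent pair; merging is separate."""
    clouds: list[PointCloud] = []
    for pair in enumerate_pairs(rig):
        base = stereo_basecloud(pair, depth_source, masks, image_provider=image_provider)
        fan = select_mask_fan(pair, rig, fan_deg)
        carved = remove_masked_points(base, fan, masks, min_bg_views=min_bg_views)
        if log is not None:
            log.append(
                {"pair": pair.tag, "built": len(base), "removed": len(base) - len(carved)}
            )
        clouds.append(carved)
    return clouds
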