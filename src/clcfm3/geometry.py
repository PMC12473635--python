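"""Pinhole camera model, triangulation and similarity transforms.

Conventions used throughout the package:

* Right-handed world frame in millimetres; the turntable axis is +Z and the
  disc plane is Z=0.
* A camera pose maps world points into the camera frame, ``x_c = R x_w + t``;
  the camera looks down its own +Z axis and its centre is ``-R.T @ t``.
* Pixels are 0-based with origin at the top-left, x right, y down, and pixel
  centres at integer coordinates.
* "Depth" always means the distance along the viewing ray (the DP quantity of
  the stereo model), not the camera-frame z coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "CameraPose",
    "View",
    "Point3D",
    "DegenerateGeometryError",
    "project",
    "project_points",
    "backproject",
    "triangulate",
    "fit_similarity",
    "look_at",
]

_ORTHO_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Raised when a geometric estimation problem is ill-posed."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Shared pinhole intrinsics with a 2-coefficient radial distortion model."""

    focal_px: float
    principal_point: tuple[float, float]
    image_size: tuple[int, int]  # (width, height)
    distortion: tuple[float, float] = (0.0, 0.0)  # (k1, k2)

    def __post_init__(self) -> None:
        w, h = self.image_size
        if not (w > 0 and h > 0 and int(w) == w and int(h) == h):
            raise ValueError(f"image_size must be positive integers, got {self.image_size}")
        if self.focal_px <= 0:
            raise ValueError(f"focal_px must be positive, got {self.focal_px}")
        px, py = self.principal_point
        if not (0 <= px < w and 0 <= py < h):
            raise ValueError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        px, py = self.principal_point
        return np.array(
            [[self.focal_px, 0.0, px], [0.0, self.focal_px, py], [0.0, 0.0, 1.0]]
        )

    def distort(self, xn: np.ndarray) -> np.ndarray:
        """Apply radial distortion to normalized coordinates (N, 2)."""
        k1, k2 = self.distortion
        if k1 == 0.0 and k2 == 0.0:
            return xn
        r2 = np.sum(xn**2, axis=-1, keepdims=True)
        return xn * (1.0 + k1 * r2 + k2 * r2**2)

    def undistort(self, xd: np.ndarray, iters: int = 10) -> np.ndarray:
        """Invert the radial model by fixed-point iteration."""
        k1, k2 = self.distortion
        if k1 == 0.0 and k2 == 0.0:
            return xd
        xn = xd.copy()
        for _ in range(iters):
            r2 = np.sum(xn**2, axis=-1, keepdims=True)
            xn = xd / (1.0 + k1 * r2 + k2 * r2**2)
        return xn


@dataclass(frozen=True)
class CameraPose:
    """World-to-camera rigid transform: ``x_cam = R @ x_world + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant")

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates, ``-R.T @ t``."""
        return -self.rotation.T @ self.translation

    def is_orthonormal(self, tol: float = _ORTHO_TOL) -> bool:
        R = self.rotation
        return bool(
            np.abs(R @ R.T - np.eye(3)).max() <= tol
            and abs(np.linalg.det(R) - 1.0) <= tol
        )

    def transform(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation


def look_at(center: np.ndarray, target: np.ndarray, up=(0.0, 0.0, 1.0)) -> CameraPose:
    """Pose of a camera at ``center`` looking towards ``target``.

    The camera +Z axis points at the target; +X is chosen perpendicular to the
    world ``up`` so image rows stay level with the turntable plane.
    """
    center = np.asarray(center, dtype=float)
    z = np.asarray(target, dtype=float) - center
    nz = np.linalg.norm(z)
    if nz == 0:
        raise ValueError("camera center coincides with the look-at target")
    z = z / nz
    up = np.asarray(up, dtype=float)
    x = np.cross(z, -up)  # pixel y runs downwards
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        x = np.cross(z, np.array([1.0, 0.0, 0.0]))
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    R = np.stack([x, y, z])  # rows = camera axes in world coords
    return CameraPose(rotation=R, translation=-R @ center)


@dataclass
class View:
    """One captured image of the ring: indices, intrinsics, (estimated) pose."""

    view_id: str
    camera_row: int
    rotation_index: int
    azimuth_deg: float
    intrinsics: CameraIntrinsics
    pose: Optional[CameraPose] = None
    image_ref: Optional[str] = None
    mask_ref: Optional[str] = None

    def with_pose(self, pose: CameraPose) -> "View":
        return replace(self, pose=pose)


@dataclass
class Point3D:
    position: np.ndarray
    color: Optional[tuple[int, int, int]] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("point coordinates must be finite")


def project_points(points: np.ndarray, view: View) -> tuple[np.ndarray, np.ndarray]:
    """Project world points (N, 3) into a view.

    Returns ``(uv, in_front)`` where ``uv`` is (N, 2) continuous pixel
    coordinates (undefined rows where ``in_front`` is False) and ``in_front``
    marks points with positive camera-frame depth.
    """
    if view.pose is None:
        raise ValueError(f"view {view.view_id} has no pose")
    pc = view.pose.transform(np.asarray(points, dtype=float))
    z = pc[:, 2]
    in_front = z > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = pc[:, :2] / z[:, None]
    xn = np.where(in_front[:, None], xn, 0.0)
    xd = view.intrinsics.distort(xn)
    uv = xd * view.intrinsics.focal_px + np.asarray(view.intrinsics.principal_point)
    return uv, in_front


def project(point, view: View) -> Optional[tuple[float, float]]:
    """Project a single point; ``None`` signals a behind-camera point."""
    pos = point.position if isinstance(point, Point3D) else np.asarray(point, float)
    uv, ok = project_points(pos.reshape(1, 3), view)
    if not ok[0]:
        return None
    return float(uv[0, 0]), float(uv[0, 1])


def pixel_rays(view: View, uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """World-frame unit ray directions through pixels ``uv`` (N, 2).

    Returns ``(origin, directions)``; the origin is the camera centre.
    """
    if view.pose is None:
        raise ValueError(f"view {view.view_id} has no pose")
    intr = view.intrinsics
    xd = (np.atleast_2d(uv) - np.asarray(intr.principal_point)) / intr.focal_px
    xn = intr.undistort(xd)
    d_cam = np.concatenate([xn, np.ones((len(xn), 1))], axis=1)
    d_cam /= np.linalg.norm(d_cam, axis=1, keepdims=True)
    d_world = d_cam @ view.pose.rotation  # R.T @ d for each row
    return view.pose.center, d_world


def backproject(view: View, uv: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Lift pixels to 3D at ray distance ``depth`` (mm along the viewing ray)."""
    origin, dirs = pixel_rays(view, uv)
    return origin + np.atleast_1d(depth)[:, None] * dirs


def triangulate(observations: Sequence[tuple[View, tuple[float, float]]]) -> Point3D:
    """Triangulate a point from >= 2 pixel observations.

    A linear midpoint/DLT initialisation is refined by Gauss-Newton on the sum
    of squared reprojection errors. Near-parallel rays (every pairwise angle
    below 1e-6 rad) raise :class:`DegenerateGeometryError`.
    """
    if len(observations) < 2:
        raise DegenerateGeometryError("triangulation needs at least two observations")
    origins = []
    dirs = []
    for view, uv in observations:
        o, d = pixel_rays(view, np.asarray(uv, dtype=float).reshape(1, 2))
        origins.append(o)
        dirs.append(d[0])
    origins = np.asarray(origins)
    dirs = np.asarray(dirs)

    spread = np.linalg.norm(origins - origins.mean(axis=0), axis=1).max()
    if spread < 1e-9:
        raise DegenerateGeometryError("all observations share one camera centre")

    dots = np.clip(np.abs(dirs @ dirs.T), -1.0, 1.0)
    angles = np.arccos(np.clip(dots, 0.0, 1.0))
    iu = np.triu_indices(len(dirs), k=1)
    if np.max(angles[iu]) < 1e-6:
        raise DegenerateGeometryError("rays are (near-)parallel; geometry is degenerate")

    # Linear init: closest point to all rays.
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for o, d in zip(origins, dirs):
        P = np.eye(3) - np.outer(d, d)
        A += P
        b += P @ o
    x = np.linalg.solve(A, b)

    # Gauss-Newton on reprojection error.
    views = [v for v, _ in observations]
    uvs = np.asarray([uv for _, uv in observations], dtype=float)
    for _ in range(20):
        r = np.zeros(2 * len(views))
        J = np.zeros((2 * len(views), 3))
        for i, view in enumerate(views):
            intr = view.intrinsics
            pc = view.pose.transform(x[None, :])[0]
            z = pc[2]
            if z <= 0:
                continue
            xn = pc[:2] / z
            xd = intr.distort(xn[None, :])[0]
            uv_hat = xd * intr.focal_px + np.asarray(intr.principal_point)
            r[2 * i : 2 * i + 2] = uv_hat - uvs[i]
            # Jacobian via the undistorted model; distortion correction is
            # small enough that GN still converges on it.
            k1, k2 = intr.distortion
            r2 = xn @ xn
            scale = 1.0 + k1 * r2 + k2 * r2 * r2
            d_xn = np.array(
                [[1.0 / z, 0.0, -xn[0] / z], [0.0, 1.0 / z, -xn[1] / z]]
            ) @ view.pose.rotation
            J[2 * i : 2 * i + 2, :] = intr.focal_px * scale * d_xn
        try:
            dx = np.linalg.solve(J.T @ J, -J.T @ r)
        except np.linalg.LinAlgError:
            break
        x = x + dx
        if np.linalg.norm(dx) < 1e-12:
            break
    return Point3D(position=x)


def fit_similarity(
    src: np.ndarray, dst: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity ``dst ~ s * R @ src + t`` (Umeyama closed form).

    Returns ``(scale, rotation, translation)``. Requires >= 3 non-collinear
    correspondences.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must both be (N, 3)")
    n = len(src)
    if n < 3:
        raise DegenerateGeometryError("similarity fit needs at least 3 points")
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    src_c = src - mu_s
    dst_c = dst - mu_d
    cov = dst_c.T @ src_c / n
    U, S, Vt = np.linalg.svd(cov)
    var_s = (src_c**2).sum() / n
    if var_s == 0 or S[1] < 1e-12 * max(S[0], 1.0):
        raise DegenerateGeometryError("source points are (near-)collinear")
    D = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        D[2, 2] = -1.0
    R = U @ D @ Vt
    s = np.trace(np.diag(S) @ D) / var_s
    t = mu_d - s * R @ mu_s
    return float(s), R, t


def apply_similarity(points: np.ndarray, s: float, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return s * np.atleast_2d(points) @ R.T + t
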