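"""Classical two-view dense stereo: epipolar rectification + ZNCC matching.

This is the image-based depth backend for pair densification: both images
are rotated onto a common rectified plane whose x-axis follows the
baseline, disparities are found by zero-mean normalized cross-correlation
over a window with a left-right consistency check, and depths are read
back on the reference view's own pixel grid. Distortion is assumed zero
here (the synthetic renders are distortion-free); undistort upstream if
needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter

from .geometry import CameraIntrinsics, CameraPose, View
from .synthetic import DepthMap

__all__ = ["rectify_pair", "zncc_disparity", "block_matching_depth"]


@dataclass
class Rectification:
    R_rect: np.ndarray      # world->rectified rotation
    K_rect: np.ndarray
    H_a: np.ndarray         # original pixel -> rectified pixel homography (view A)
    H_b: np.ndarray
    baseline: float
    size: tuple[int, int]   # (width, height)


def rectify_pair(view_a: View, view_b: View) -> Rectification:
    """Fusiello-style rectifying rotation for two posed pinhole views."""
    ca, cb = view_a.pose.center, view_b.pose.center
    baseline = np.linalg.norm(cb - ca)
    if baseline < 1e-9:
        raise ValueError("coincident camera centres cannot be rectified")
    x = (cb - ca) / baseline
    za = view_a.pose.rotation[2]
    z = za - (za @ x) * x
    z /= np.linalg.norm(z)
    y = np.cross(z, x)
    R_rect = np.stack([x, y, z])
    K = view_a.intrinsics.K
    H_a = K @ R_rect @ view_a.pose.rotation.T @ np.linalg.inv(view_a.intrinsics.K)
    H_b = K @ R_rect @ view_b.pose.rotation.T @ np.linalg.inv(view_b.intrinsics.K)
    w, h = view_a.intrinsics.image_size
    return Rectification(R_rect, K, H_a, H_b, float(baseline), (w, h))


def _warp(gray: np.ndarray, H_inv: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    w, h = size
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    ones = np.ones_like(uu)
    src = H_inv @ np.stack([uu.ravel(), vv.ravel(), ones.ravel()])
    src = src[:2] / src[2]
    return map_coordinates(gray, [src[1].reshape(h, w), src[0].reshape(h, w)], order=1, cval=np.nan)


def zncc_disparity(
    left: np.ndarray,
    right: np.ndarray,
    d_min: int,
    d_max: int,
    window: int = 7,
    lr_max: float = 1.0,
    zncc_min: float = 0.3,
) -> np.ndarray:
    """Disparity of the left image w.r.t. the right (x_left - x_right >= 0).

    ZNCC over a square window, winner-take-all with parabolic sub-pixel
    refinement and a left-right consistency check; NaN marks rejected pixels.
    """
    h, w = left.shape
    disparities = np.arange(d_min, d_max + 1)
    cost_l = np.full((len(disparities), h, w), -np.inf, dtype=np.float32)

    def zncc_for_shift(a, b):
        valid = np.isfinite(a) & np.isfinite(b)
        a0 = np.where(valid, a, 0.0)
        b0 = np.where(valid, b, 0.0)
        mu_a = uniform_filter(a0, window)
        mu_b = uniform_filter(b0, window)
        aa = uniform_filter(a0 * a0, window) - mu_a**2
        bb = uniform_filter(b0 * b0, window) - mu_b**2
        ab = uniform_filter(a0 * b0, window) - mu_a * mu_b
        denom = np.sqrt(np.clip(aa * bb, 1e-12, None))
        score = ab / denom
        score[~valid] = -np.inf
        return score

    for k, d in enumerate(disparities):
        shifted = np.full_like(right, np.nan)
        if d == 0:
            shifted = right
        elif d > 0:
            shifted[:, d:] = right[:, :-d]
        cost_l[k] = zncc_for_shift(left, shifted)

    best = np.argmax(cost_l, axis=0)
    best_score = np.take_along_axis(cost_l, best[None], axis=0)[0]
    disp_l = disparities[best].astype(float)
    # parabolic sub-pixel
    interior = (best > 0) & (best < len(disparities) - 1)
    c0 = np.take_along_axis(cost_l, np.clip(best - 1, 0, None)[None], axis=0)[0]
    c2 = np.take_along_axis(cost_l, np.clip(best + 1, None, len(disparities) - 1)[None], axis=0)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = c0 - 2 * best_score + c2
        frac = 0.5 * (c0 - c2) / denom
    frac = np.where(interior & np.isfinite(frac) & (np.abs(frac) <= 1), frac, 0.0)
    disp_l = disp_l + frac

    # right-image disparity for the consistency check
    cost_r = np.full_like(cost_l, -np.inf)
    for k, d in enumerate(disparities):
        shifted = np.full_like(left, np.nan)
        if d == 0:
            shifted = left
        elif d > 0:
            shifted[:, :-d] = left[:, d:]
        cost_r[k] = zncc_for_shift(right, shifted)
    disp_r = disparities[np.argmax(cost_r, axis=0)].astype(float)

    uu = np.arange(w)[None, :].repeat(h, axis=0)
    xr = np.clip(np.round(uu - disp_l).astype(int), 0, w - 1)
    lr = np.abs(disp_l - disp_r[np.arange(h)[:, None], xr])
    bad = (best_score < zncc_min) | (lr > lr_max) | ~np.isfinite(best_score)
    disp_l[bad] = np.nan
    return disp_l


def block_matching_depth(
    view_a: View,
    view_b: View,
    image_a: np.ndarray,
    image_b: np.ndarray,
    depth_range: tuple[float, float] = (300.0, 3000.0),
    window: int = 7,
    zncc_min: float = 0.3,
) -> DepthMap:
    """Dense ray-depth for ``view_a`` from a rectified ZNCC disparity map."""
    rect = rectify_pair(view_a, view_b)
    gray_a = image_a.mean(axis=2) if image_a.ndim == 3 else image_a.astype(float)
    gray_b = image_b.mean(axis=2) if image_b.ndim == 3 else image_b.astype(float)
    ra = _warp(gray_a, np.linalg.inv(rect.H_a), rect.size)
    rb = _warp(gray_b, np.linalg.inv(rect.H_b), rect.size)
    f = rect.K_rect[0, 0]
    z_min, z_max = depth_range
    d_max = int(np.ceil(f * rect.baseline / z_min))
    d_min = max(0, int(np.floor(f * rect.baseline / z_max)))
    # matching direction depends on which rectified image is "left"
    ca, cb = view_a.pose.center, view_b.pose.center
    a_is_left = True  # by construction x axis points from a to b => b shifts left
    disp = zncc_disparity(ra, rb, d_min, d_max, window=window, zncc_min=zncc_min)

    w, h = rect.size
    # rectified z for each rectified pixel, then world point, then ray depth
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = f * rect.baseline / disp
    K_inv = np.linalg.inv(rect.K_rect)
    pix = np.stack([uu.ravel(), vv.ravel(), np.ones(w * h)])
    rays = (K_inv @ pix).T
    pts = rays * z.ravel()[:, None]
    world = pts @ rect.R_rect + ca  # R_rect.T applied row-wise, then translate

    # resample onto the original reference grid: map original pixels through H_a
    ou, ov = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    src = rect.H_a @ np.stack([ou.ravel(), ov.ravel(), np.ones(w * h)])
    src = src[:2] / src[2]
    depth_rect = np.linalg.norm(world - ca, axis=1).reshape(h, w)
    depth_rect[~np.isfinite(z)] = np.nan
    sampled = map_coordinates(depth_rect, [src[1], src[0]], order=0, cval=np.nan)
    values = sampled.reshape(h, w)
    values[~np.isfinite(values)] = np.inf
    return DepthMap(values=values)
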