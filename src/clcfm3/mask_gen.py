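"""Silhouette mask generation by nearest-reference-color classification.

Each pixel is assigned to foreground (plant) or background by comparing its
color against the mean of user-supplied reference pixels for each class —
the blue-screen studio makes this a reliable two-class nearest-mean rule.
Ties go to background (prefer losing a boundary pixel to keeping noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab
from skimage.morphology import binary_closing, binary_opening, disk

from .synthetic import MaskImage

__all__ = ["RefColorModel", "build_reference_model", "classify_image"]


@dataclass(frozen=True)
class RefColorModel:
    fg_mean: tuple[float, float, float]
    bg_mean: tuple[float, float, float]

    def __post_init__(self) -> None:
        for c in (*self.fg_mean, *self.bg_mean):
            if not (0 <= c <= 255):
                raise ValueError("reference channel values must be in [0, 255]")


def build_reference_model(fg_pixels, bg_pixels) -> RefColorModel:
    """Per-class mean colors from reference pixel sets (any iterable of RGB)."""
    fg = np.asarray(list(fg_pixels), dtype=float).reshape(-1, 3)
    bg = np.asarray(list(bg_pixels), dtype=float).reshape(-1, 3)
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("both reference pixel sets must be non-empty")
    return RefColorModel(fg_mean=tuple(fg.mean(axis=0)), bg_mean=tuple(bg.mean(axis=0)))


def classify_image(
    image: np.ndarray,
    model: RefColorModel,
    metric: str = "rgb",
    cleanup_radius: int = 0,
) -> MaskImage:
    """Classify each pixel: 1 iff strictly closer to the foreground mean.

    ``metric`` is Euclidean distance in RGB by default; ``"lab"`` switches to
    CIELAB. ``cleanup_radius`` > 0 applies a morphological open then close
    with a disk of that radius.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be (H, W, 3) RGB")
    fg = np.asarray(model.fg_mean, float)
    bg = np.asarray(model.bg_mean, float)
    if metric == "lab":
        stack = np.concatenate([img.reshape(-1, 3), fg[None, :], bg[None, :]])
        lab = rgb2lab((stack / 255.0).reshape(-1, 1, 3)).reshape(-1, 3)
        px, fg, bg = lab[:-2], lab[-2], lab[-1]
        d_fg = np.sum((px - fg) ** 2, axis=1).reshape(img.shape[:2])
        d_bg = np.sum((px - bg) ** 2, axis=1).reshape(img.shape[:2])
    elif metric == "rgb":
        d_fg = np.sum((img - fg) ** 2, axis=2)
        d_bg = np.sum((img - bg) ** 2, axis=2)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    mask = d_fg < d_bg  # tie -> background
    if cleanup_radius > 0:
        se = disk(cleanup_radius)
        mask = binary_closing(binary_opening(mask, se), se)
    return MaskImage(values=mask.astype(np.uint8))
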