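"""Metric validation of a reconstruction via coded targets.

The reconstruction frame produced by SfM is defined only up to a similarity
transform, so metric statements need a scale: it is fitted from one or more
target pairs of known physical separation, then the remaining inter-target
distances are measured in the scaled reconstruction and compared against
ground truth. Repeating the whole pipeline over seeds yields per-pair mean,
SD and difference statistics against a 1 mm accuracy goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import DegenerateGeometryError, View, project_points, triangulate
from .synthetic import RigSequence, SceneModel

__all__ = [
    "TargetObservation",
    "fit_scale",
    "measure_pair",
    "accuracy_report",
    "triangulate_targets",
]


@dataclass
class TargetObservation:
    target_id: int
    position: np.ndarray  # reconstruction coordinates
    gt_position: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float).reshape(3)


def fit_scale(
    observed: dict[int, np.ndarray],
    known_pairs: Sequence[tuple[int, int, float]],
) -> float:
    """Least-squares scale s minimizing sum (s * d_obs - d_known)^2.

    Closed form: s = sum(d_obs * d_known) / sum(d_obs^2) over the usable
    pairs (both endpoints observed).
    """
    num = 0.0
    den = 0.0
    used = 0
    for ida, idb, d_known in known_pairs:
        if ida not in observed or idb not in observed:
            continue
        d_obs = float(np.linalg.norm(np.asarray(observed[ida]) - np.asarray(observed[idb])))
        num += d_obs * d_known
        den += d_obs * d_obs
        used += 1
    if used == 0 or den == 0.0:
        raise ValueError("no usable target pair with nonzero observed distance")
    return num / den


def measure_pair(observed: dict[int, np.ndarray], ida: int, idb: int, scale: float = 1.0) -> float:
    """Scaled Euclidean distance between two observed targets (mm)."""
    for tid in (ida, idb):
        if tid not in observed:
            raise KeyError(f"target {tid} not observed")
    return scale * float(np.linalg.norm(np.asarray(observed[ida]) - np.asarray(observed[idb])))


def triangulate_targets(
    scene: SceneModel,
    rig: RigSequence,
    estimated_views: Sequence[View],
    noise_sigma_px: float = 0.0,
    seed: int = 0,
    min_views: int = 3,
) -> dict[int, np.ndarray]:
    """Localize coded targets in the reconstruction frame.

    The targets' image coordinates are known exactly in the captured images
    (projections through the ground-truth poses, optionally with detection
    noise); triangulating those pixels through the *estimated* poses places
    each target in the reconstruction's own similarity frame — the same
    information an image-based coded-target detector would provide.
    """
    rng = np.random.default_rng(seed)
    est_by_id = {v.view_id: v for v in estimated_views if v.pose is not None}
    out: dict[int, np.ndarray] = {}
    for tid, pos in scene.coded_targets:
        obs = []
        for view in rig.views:
            if view.view_id not in est_by_id:
                continue
            gt = rig.gt_view(view)
            uv, ok = project_points(pos[None, :], gt)
            if not ok[0]:
                continue
            u, v = uv[0]
            w, h = view.intrinsics.image_size
            if not (0 <= u < w and 0 <= v < h):
                continue
            if noise_sigma_px > 0:
                u += rng.normal(0, noise_sigma_px)
                v += rng.normal(0, noise_sigma_px)
            obs.append((est_by_id[view.view_id], (float(u), float(v))))
        if len(obs) >= max(2, min_views):
            try:
                out[tid] = triangulate(obs).position
            except DegenerateGeometryError:
                continue
    return out


def accuracy_report(
    runs: Sequence[dict[tuple[int, int], float]],
    ground_truth: dict[tuple[int, int], float],
) -> dict:
    """Per-pair mean/SD over repeated runs and difference vs ground truth.

    ``runs`` holds one {pair: measured distance mm} mapping per repetition;
    all runs must measure the same pair set. SD is the population SD of the
    repeated measurements; ``difference`` is ground truth minus mean.
    """
    if not runs:
        raise ValueError("at least one run required")
    pair_set = set(runs[0])
    for i, run in enumerate(runs[1:], start=2):
        if set(run) != pair_set:
            raise ValueError(f"run {i} measures a different pair set")
    rows = []
    diffs = []
    for pair in sorted(pair_set):
        vals = np.array([run[pair] for run in runs], float)
        mean = float(vals.mean())
        sd = float(vals.std())
        gt = ground_truth.get(pair)
        diff = None if gt is None else gt - mean
        if diff is not None:
            diffs.append(abs(diff))
        rows.append(
            {"pair": list(pair), "mean_mm": mean, "sd_mm": sd,
             "ground_truth_mm": gt, "difference_mm": diff}
        )
    return {
        "pairs": rows,
        "n_runs": len(runs),
        "max_abs_difference_mm": max(diffs) if diffs else math.nan,
        "mean_abs_difference_mm": float(np.mean(diffs)) if diffs else math.nan,
    }
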