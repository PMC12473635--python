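import numpy as np
import pytest

from clcfm3.cloud import PointCloud, merge
from clcfm3.geometry import project_points
from clcfm3.mmm import (
    OracleDepthSource,
    enumerate_pairs,
    mmm_run,
    remove_masked_points,
    select_mask_fan,
    stereo_basecloud,
)
from clcfm3.synthetic import (
    Box,
    MaskImage,
    SceneModel,
    build_turntable_rig,
    inject_flying_pixels,
    render_mask,
    sample_surface_points,
)


@pytest.fixture(scope="module")
def rig72x4():
    return build_turntable_rig(n_rotations=72, step_deg=5.0, camera_rows=4)


def _in_hull(point, rig, masks):
    """True iff every in-bounds, in-front projection lands on foreground."""
    for v in rig.views:
        gv = rig.gt_view(v)
        uv, front = project_points(point[None, :], gv)
        if not front[0]:
            continue
        m = masks[v.view_id].values
        h, w = m.shape
        ui, vi = int(round(uv[0, 0])), int(round(uv[0, 1]))
        if 0 <= ui < w and 0 <= vi < h and m[vi, ui] == 0:
            return False
    return True


class TestEnumeratePairs:
    def test_full_rig_has_one_job_per_row_rotation(self, rig72x4):
        assert len(enumerate_pairs(rig72x4)) == 288

    def test_wraparound_pair_present(self, rig8):
        rots = [j.rotations for j in enumerate_pairs(rig8)]
        assert rots == [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 0)]

    def test_single_rotation_rejected(self):
        with pytest.raises(ValueError, match="adjacency"):
            enumerate_pairs(build_turntable_rig(n_rotations=1, step_deg=360.0, camera_rows=1))

    def test_unaligned_views_rejected(self, rig8):
        import copy

        rig = copy.deepcopy(rig8)
        rig.views[3].pose = None
        with pytest.raises(ValueError, match=rig.views[3].view_id):
            enumerate_pairs(rig)


class TestMaskFan:
    def test_default_fan_selects_72_masks(self, rig72x4):
        """72 stops x 5 deg x 4 rows with the 90-degree fan: 18 rotation
        stops x 4 rows = 72 mask views, for every pair."""
        for job in enumerate_pairs(rig72x4)[:8]:
            assert len(select_mask_fan(job, rig72x4, 90.0)) == 72

    def test_full_fan_selects_all(self, rig72x4):
        job = enumerate_pairs(rig72x4)[0]
        assert len(select_mask_fan(job, rig72x4, 360.0)) == 288

    def test_zero_fan_empty(self, rig72x4):
        job = enumerate_pairs(rig72x4)[0]
        assert select_mask_fan(job, rig72x4, 0.0) == []

    def test_own_views_included(self, rig24):
        job = enumerate_pairs(rig24)[0]
        ids = {v.view_id for v in select_mask_fan(job, rig24, 90.0)}
        assert job.view_a.view_id in ids and job.view_b.view_id in ids

    def test_invalid_angle(self, rig24):
        with pytest.raises(ValueError):
            select_mask_fan(enumerate_pairs(rig24)[0], rig24, 400.0)


class TestBaseCloud:
    def test_oracle_plane_accuracy(self):
        """Oracle depth on a textured slab: backprojected points lie on the
        slab surface to sub-0.2 mm."""
        slab = Box((0.0, 0.0, 200.0), (120.0, 4.0, 120.0))
        scene = SceneModel(plant=[slab], structures=[], coded_targets=[])
        rig = build_turntable_rig(n_rotations=24, step_deg=15.0, camera_rows=1,
                                  distance=700.0, target_height_range=(0.0, 400.0))
        masks = {v.view_id: render_mask(scene, rig.gt_view(v)) for v in rig.views}
        job = [j for j in enumerate_pairs(rig) if j.rotations == (6, 7)][0]
        cloud = stereo_basecloud(job, OracleDepthSource(scene, rig), masks)
        assert len(cloud) > 1000
        # signed distance to the axis-aligned box surface
        q = np.abs(cloud.positions - np.array([0.0, 0.0, 200.0])) - np.array([120.0, 4.0, 120.0])
        sdf = np.linalg.norm(np.maximum(q, 0.0), axis=1) + np.minimum(q.max(axis=1), 0.0)
        assert (np.abs(sdf) < 0.2).mean() >= 0.99

    def test_all_zero_mask_gives_empty_cloud(self, scene, rig24):
        job = enumerate_pairs(rig24)[0]
        w, h = rig24.views[0].intrinsics.image_size
        masks = {v.view_id: MaskImage(values=np.zeros((h, w), np.uint8)) for v in rig24.views}
        cloud = stereo_basecloud(job, OracleDepthSource(scene, rig24), masks)
        assert len(cloud) == 0

    def test_points_tagged_with_pair(self, scene, rig24, masks24):
        job = enumerate_pairs(rig24)[0]
        cloud = stereo_basecloud(job, OracleDepthSource(scene, rig24), masks24)
        assert (cloud.tags == job.tag).all()


class TestRemoveMaskedPoints:
    def test_point_outside_every_silhouette_removed(self, scene, rig24, masks24):
        stray = PointCloud(positions=np.array([[500.0, 500.0, 50.0]]))
        out = remove_masked_points(stray, [rig24.gt_view(v) for v in rig24.views], masks24)
        assert len(out) == 0

    def test_hull_consistent_points_kept(self, scene, rig24, masks24):
        """Carving soundness: a point whose projections land on foreground in
        all fan views is never removed."""
        samples = sample_surface_points(scene, 400, seed=11)
        views = [rig24.gt_view(v) for v in rig24.views]
        keep_expected = np.array(
            [_in_hull(p, rig24, masks24) for p in samples.positions]
        )
        out = remove_masked_points(samples, views, masks24)
        kept = {tuple(p) for p in out.positions}
        for p, expect in zip(samples.positions, keep_expected):
            assert (tuple(p) in kept) == expect

    def test_fan_nesting(self, scene, rig24, masks24):
        """Removal sets are nested across growing fans 50 -> 90 -> 180 -> 360
        degrees (the noise/defect trade-off, formalized)."""
        cloud = inject_flying_pixels(
            sample_surface_points(scene, 380, seed=12), scene, rig24.views,
            n=120, depth_perturbation=25.0, seed=13,
        )
        job = enumerate_pairs(rig24)[0]
        removed_prev: set = set()
        for fan in (50.0, 90.0, 180.0, 360.0):
            views = select_mask_fan(job, rig24, fan)
            out = remove_masked_points(cloud, views, masks24)
            kept = {tuple(p) for p in out.positions}
            removed = {tuple(p) for p in cloud.positions} - kept
            assert removed_prev <= removed
            removed_prev = removed

    def test_abstention_of_views_that_cannot_see(self, rig24, masks24):
        """A point behind every camera is never voted on, hence kept."""
        # rig cameras all look inward from radius 700: a point far outside
        # projects out of bounds or behind for every view
        far = PointCloud(positions=np.array([[0.0, 0.0, 99999.0]]))
        out = remove_masked_points(far, [rig24.gt_view(v) for v in rig24.views], masks24)
        assert len(out) == 1

    def test_missing_mask_error_names_view(self, scene, rig24, masks24):
        cloud = sample_surface_points(scene, 10, seed=14)
        broken = dict(masks24)
        victim = rig24.views[5].view_id
        del broken[victim]
        with pytest.raises(FileNotFoundError, match=victim):
            remove_masked_points(cloud, [rig24.gt_view(v) for v in rig24.views], broken)


class TestMmmRun:
    def test_merged_result_inside_visual_hull_at_full_fan(self, scene, rig24, masks24):
        """With a 360-degree fan every surviving point projects to foreground
        in every view (the visual-hull guarantee)."""
        clouds = mmm_run(rig24, OracleDepthSource(scene, rig24), masks24, fan_deg=360.0)
        merged = merge(clouds)
        assert len(merged) > 0
        rng = np.random.default_rng(0)
        idx = rng.choice(len(merged), size=min(300, len(merged)), replace=False)
        for p in merged.positions[idx]:
            assert _in_hull(p, rig24, masks24)

    def test_injected_noise_fully_removed_at_full_fan(self, scene, rig24, masks24):
        flying = inject_flying_pixels(
            PointCloud.empty(), scene, rig24.views, n=100, depth_perturbation=25.0, seed=15
        )
        outside = [p for p in flying.positions if not _in_hull(p, rig24, masks24)]
        views = [rig24.gt_view(v) for v in rig24.views]
        out = remove_masked_points(
            PointCloud(positions=np.array(outside)), views, masks24
        )
        assert len(out) == 0  # 100% of out-of-hull noise removed

    def test_wider_fan_removes_at_least_as_much_noise(self, scene, rig24, masks24):
        flying = inject_flying_pixels(
            PointCloud.empty(), scene, rig24.views, n=150, depth_perturbation=25.0, seed=16
        )
        job = enumerate_pairs(rig24)[0]
        kept = {}
        for fan in (50.0, 90.0):
            views = select_mask_fan(job, rig24, fan)
            kept[fan] = len(remove_masked_points(flying, views, masks24))
        assert kept[90.0] <= kept[50.0]

    def test_tags_survive_carving(self, scene, rig24, masks24):
        clouds = mmm_run(rig24, OracleDepthSource(scene, rig24), masks24, fan_deg=90.0)
        for c, job in zip(clouds, enumerate_pairs(rig24)):
            if len(c):
                assert (c.tags == job.tag).all()
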