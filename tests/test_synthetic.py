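import numpy as np
import pytest

from clcfm3.cloud import PointCloud
from clcfm3.frontend import detect_corners
from clcfm3.geometry import project_points
from clcfm3.synthetic import (
    DEFAULT_BACKGROUND_RGB,
    Sphere,
    SceneModel,
    boundary_pixels,
    build_plant_scene,
    build_turntable_rig,
    inject_flying_pixels,
    render_depth,
    render_mask,
    render_texture_image,
    sample_surface_points,
)


class TestBuildPlantScene:
    def test_deterministic_for_seed(self):
        a = build_plant_scene(seed=7)
        b = build_plant_scene(seed=7)
        assert len(a.plant) == len(b.plant)
        for pa, pb in zip(a.plant, b.plant):
            assert pa == pb
        assert all(
            ta == tb and np.allclose(pa, pb)
            for (ta, pa), (tb, pb) in zip(a.coded_targets, b.coded_targets)
        )

    def test_bare_stage_has_only_structure(self):
        s = build_plant_scene(n_stems=0, n_leaves=0, seed=1)
        assert s.plant == []
        assert len(s.structures) == 4  # disc + 3 pillars
        assert len(s.coded_targets) > 9

    def test_target_layout(self, scene):
        pos = scene.target_positions()
        np.testing.assert_allclose(pos[0], [0, 0, 0])
        for k in range(1, 9):
            assert np.linalg.norm(pos[k]) == pytest.approx(150.0)
            assert pos[k][2] == 0.0
        # pillar targets are stacked 200 mm apart
        assert np.linalg.norm(pos[102] - pos[101]) == pytest.approx(200.0)
        assert pos[101][2] == pytest.approx(200.0)

    def test_nonphysical_params_rejected(self):
        with pytest.raises(ValueError):
            build_plant_scene(stem_radius=-1.0, seed=0)
        with pytest.raises(ValueError):
            build_plant_scene(n_leaves=-2, seed=0)

    def test_leaf_silhouettes_overlap_from_some_azimuth(self, scene, rig24):
        """The default plant is cluttered enough that leaves overlap stems or
        other leaves in at least one view (the occlusion regime of interest)."""
        leaves = [p for p in scene.plant if type(p).__name__ == "EllipseDisc"]
        assert len(leaves) >= 2
        found = False
        for view in rig24.views[::4]:
            gv = rig24.gt_view(view)
            total = 0
            for leaf in leaves:
                single = SceneModel(plant=[leaf], structures=[], coded_targets=[])
                total += render_mask(single, gv).values.sum()
            all_mask = render_mask(
                SceneModel(plant=leaves, structures=[], coded_targets=[]), gv
            ).values.sum()
            if all_mask < total:  # overlap shrinks the union
                found = True
                break
        assert found


class TestRig:
    def test_counts(self):
        rig = build_turntable_rig(n_rotations=72, step_deg=5.0, camera_rows=4)
        assert len(rig.views) == 288

    def test_eight_stop_azimuths(self, rig8):
        azs = sorted(v.azimuth_deg for v in rig8.views)
        assert azs == [0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0]

    def test_rows_have_distinct_centers(self):
        rig = build_turntable_rig(n_rotations=8, step_deg=45.0, camera_rows=2,
                                  heights=[200.0, 500.0])
        v0 = rig.views[0]
        twin = [v for v in rig.views if v.rotation_index == 0 and v.camera_row == 1][0]
        assert not np.allclose(rig.gt_poses[v0.view_id].center,
                               rig.gt_poses[twin.view_id].center)

    def test_inconsistent_step_rejected(self):
        with pytest.raises(ValueError):
            build_turntable_rig(n_rotations=10, step_deg=5.0)

    def test_azimuth_matches_rotation_index(self, rig24):
        for v in rig24.views:
            assert v.azimuth_deg == pytest.approx((v.rotation_index * 15.0) % 360.0)

    def test_ring_closure_constant_gap(self, rig24):
        azs = np.sort([v.azimuth_deg for v in rig24.row(0)])
        gaps = np.diff(np.append(azs, azs[0] + 360.0))
        np.testing.assert_allclose(gaps, 15.0)


class TestRender:
    def test_empty_scene(self, rig8):
        empty = SceneModel(plant=[], structures=[], coded_targets=[])
        view = rig8.gt_view(rig8.views[0])
        assert render_mask(empty, view).values.sum() == 0
        assert not render_depth(empty, view).valid.any()

    def test_sphere_silhouette_and_depth(self, rig8):
        """Sphere on the axis: silhouette contains every projected surface
        point and the central depth equals distance-to-centre minus radius."""
        R = 60.0
        center = np.array([0.0, 0.0, 200.0])
        sph = SceneModel(plant=[Sphere(tuple(center), R)], structures=[], coded_targets=[])
        view = rig8.gt_view(rig8.views[0])
        mask = render_mask(sph, view)
        depth = render_depth(sph, view)
        rng = np.random.default_rng(3)
        v = rng.normal(size=(1000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        # keep samples strictly on the camera-facing hemisphere interior
        cam = view.pose.center
        facing = (v @ (cam - center)) / np.linalg.norm(cam - center) > 0.2
        pts = center + R * v[facing]
        uv, ok = project_points(pts, view)
        assert ok.all()
        ui = np.round(uv[:, 0]).astype(int)
        vi = np.round(uv[:, 1]).astype(int)
        # allow one pixel of silhouette rasterization slack at the limb
        from scipy.ndimage import binary_dilation

        dil = binary_dilation(mask.values, iterations=1)
        assert dil[vi, ui].all()
        assert (mask.values[vi, ui] == 1).mean() > 0.95
        uc, vc = project_points(center[None, :], view)[0][0]
        d_center = depth.values[int(round(vc)), int(round(uc))]
        assert d_center == pytest.approx(np.linalg.norm(cam - center) - R, abs=0.5)

    def test_mask_depth_consistency(self, scene, rig24):
        view = rig24.gt_view(rig24.views[3])
        mask = render_mask(scene, view)
        depth = render_depth(scene, view)
        np.testing.assert_array_equal(depth.valid, mask.values.astype(bool))

    def test_texture_background_and_determinism(self, scene, rig24):
        view = rig24.gt_view(rig24.views[0])
        img1 = render_texture_image(scene, view, seed=5)
        img2 = render_texture_image(scene, view, seed=5)
        np.testing.assert_array_equal(img1, img2)
        assert tuple(img1[0, 0]) == DEFAULT_BACKGROUND_RGB
        assert len(detect_corners(img1)) >= 200


class TestSurfaceSamples:
    def test_deterministic(self, scene):
        a = sample_surface_points(scene, 100, seed=4)
        b = sample_surface_points(scene, 100, seed=4)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_single_point(self, scene):
        assert len(sample_surface_points(scene, 1, seed=0)) == 1

    def test_empty_plant_errors(self):
        bare = build_plant_scene(n_stems=0, n_leaves=0, seed=0)
        with pytest.raises(ValueError):
            sample_surface_points(bare, 10, seed=0)

    def test_sphere_mean_radius(self):
        R = 80.0
        sph = SceneModel(plant=[Sphere((0.0, 0.0, 100.0), R)], structures=[], coded_targets=[])
        pts = sample_surface_points(sph, 4000, seed=9).positions
        radii = np.linalg.norm(pts - np.array([0.0, 0.0, 100.0]), axis=1)
        assert radii.mean() == pytest.approx(R, rel=0.01)


class TestFlyingPixels:
    def test_zero_noise_is_identity(self, scene, rig24):
        base = sample_surface_points(scene, 50, seed=1)
        out = inject_flying_pixels(base, scene, rig24.views[:3], n=0, seed=2)
        assert out is base

    def test_injected_points_sit_on_silhouette_boundary(self, scene, rig24):
        """Each flying pixel keeps a boundary ray: its projection into some
        source view is within 1 px of the silhouette boundary."""
        base = PointCloud.empty()
        views = rig24.views[:4]
        out = inject_flying_pixels(base, scene, views, n=40, depth_perturbation=25.0, seed=3)
        assert len(out) == 40
        assert (out.tags == "flying").all()
        edges = {}
        for v in views:
            edges[v.view_id] = boundary_pixels(render_mask(scene, rig24.gt_view(v)))
        ok = 0
        for p in out.positions:
            for v in views:
                uv, front = project_points(p[None, :], rig24.gt_view(v))
                if not front[0]:
                    continue
                d = np.abs(edges[v.view_id] - uv[0]).max(axis=1).min()
                if d <= 1.0:
                    ok += 1
                    break
        assert ok == len(out)

    def test_large_perturbation_leaves_visual_hull(self, scene, rig24, masks24):
        """Pushed 20 mm off a thin-stem scene, nearly all flying pixels fall
        outside the 360-degree visual hull (brute-force over all masks)."""
        out = inject_flying_pixels(
            PointCloud.empty(), scene, rig24.views, n=120, depth_perturbation=25.0, seed=5
        )
        outside = 0
        for p in out.positions:
            for v in rig24.views:
                gv = rig24.gt_view(v)
                uv, front = project_points(p[None, :], gv)
                m = masks24[v.view_id].values
                h, w = m.shape
                ui, vi = int(round(uv[0, 0])), int(round(uv[0, 1]))
                if front[0] and 0 <= ui < w and 0 <= vi < h and m[vi, ui] == 0:
                    outside += 1
                    break
        assert outside / len(out) >= 0.9

    def test_no_boundary_errors(self, rig8):
        empty = SceneModel(plant=[], structures=[], coded_targets=[])
        with pytest.raises(ValueError):
            inject_flying_pixels(PointCloud.empty(), empty, rig8.views[:2], n=5, seed=0)
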