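import numpy as np
import pytest

from clcfm3.frontend import OracleFrontEnd
from clcfm3.geometry import apply_similarity, fit_similarity
from clcfm3.sfm import (
    AlignConfig,
    AlignState,
    align_increment,
    assign_groups,
    clcfm_run,
    compute_group_order,
)
from clcfm3.synthetic import build_turntable_rig


def _pose_errors(state, rig):
    """Camera-centre errors (mm) after similarity alignment to ground truth."""
    vids = sorted(state.poses)
    est = np.stack([state.poses[v].center for v in vids])
    gt = np.stack([rig.gt_poses[v].center for v in vids])
    s, R, t = fit_similarity(est, gt)
    return np.linalg.norm(apply_similarity(est, s, R, t) - gt, axis=1)


class TestAssignGroups:
    def test_decimation_72_into_6(self):
        rig = build_turntable_rig(n_rotations=72, step_deg=5.0, camera_rows=1)
        groups = assign_groups(rig, 6)
        g1 = sorted(v.rotation_index for v in groups[0].views)
        assert g1 == list(range(0, 72, 6))
        assert len(groups[0].views) == 12
        # group 4 azimuths sit halfway between adjacent group-1 azimuths
        g1_az = sorted(v.azimuth_deg for v in groups[0].views)
        for v in groups[3].views:
            below = max((a for a in g1_az if a < v.azimuth_deg), default=g1_az[-1] - 360.0)
            above = min((a for a in g1_az if a > v.azimuth_deg), default=g1_az[0] + 360.0)
            assert v.azimuth_deg == pytest.approx((below + above) / 2)

    def test_single_group_contains_all(self, rig24):
        groups = assign_groups(rig24, 1)
        assert len(groups) == 1 and len(groups[0].views) == 24

    def test_groups_partition_views(self, rig24):
        groups = assign_groups(rig24, 6)
        ids = [v.view_id for g in groups for v in g.views]
        assert sorted(ids) == sorted(v.view_id for v in rig24.views)

    def test_singleton_groups(self):
        rig = build_turntable_rig(n_rotations=6, step_deg=60.0, camera_rows=1)
        groups = assign_groups(rig, 6)
        assert all(len(g.views) == 1 for g in groups)

    def test_all_rows_share_rotation_group(self):
        rig = build_turntable_rig(n_rotations=12, step_deg=30.0, camera_rows=3)
        groups = assign_groups(rig, 4)
        for g in groups:
            rots = {v.rotation_index for v in g.views}
            for r in rots:
                rows = [v.camera_row for v in g.views if v.rotation_index == r]
                assert sorted(rows) == [0, 1, 2]

    def test_too_many_groups_rejected(self, rig8):
        with pytest.raises(ValueError):
            assign_groups(rig8, 9)


class TestGroupOrder:
    @pytest.mark.parametrize(
        "G,expected",
        [(6, [1, 4, 2, 5, 3, 6]), (1, [1]), (4, [1, 3, 2, 4]), (5, [1, 4, 2, 5, 3])],
    )
    def test_worked_examples(self, G, expected):
        assert compute_group_order(G) == expected

    @pytest.mark.parametrize("G", range(1, 13))
    def test_is_permutation(self, G):
        assert sorted(compute_group_order(G)) == list(range(1, G + 1))

    def test_even_spread_after_two_stages(self):
        """After processing the first two groups of G=4 the covered azimuths
        alternate: no two consecutive processed groups are adjacent."""
        order = compute_group_order(4)
        assert abs(order[1] - order[0]) == 2

    def test_invalid_G(self):
        with pytest.raises(ValueError):
            compute_group_order(0)


class TestAlignment:
    def test_noise_free_recovery(self, scene, rig24):
        """Oracle correspondences, no noise: every view registers and the
        poses match ground truth to numerical precision (after similarity)."""
        fe = OracleFrontEnd(scene, rig24, n_points=200, noise_sigma_px=0.0, seed=1)
        state = clcfm_run(rig24, G=6, front_end=fe,
                          config=AlignConfig(intrinsics_init=rig24.views[0].intrinsics))
        assert len(state.poses) == 24
        assert state.rmse_px < 1e-6
        rig_radius = 700.0
        err = _pose_errors(state, rig24)
        assert np.sqrt((err**2).mean()) < 1e-6 * rig_radius

    def test_per_rotation_groups_degenerate_case(self, scene, rig8):
        """G = n_rotations reduces CLCFM to per-view incremental SfM and
        still registers the whole ring on noise-free data."""
        fe = OracleFrontEnd(scene, rig8, n_points=200, noise_sigma_px=0.0, seed=2)
        state = clcfm_run(rig8, G=8, front_end=fe,
                          config=AlignConfig(intrinsics_init=rig8.views[0].intrinsics))
        assert len(state.poses) == 8
        assert state.rmse_px < 1e-6

    def test_determinism(self, scene, rig8):
        fe = OracleFrontEnd(scene, rig8, n_points=150, noise_sigma_px=0.3, seed=3)
        cfg = AlignConfig(intrinsics_init=rig8.views[0].intrinsics)
        s1 = clcfm_run(rig8, G=4, front_end=fe, config=cfg)
        s2 = clcfm_run(rig8, G=4, front_end=fe, config=cfg)
        for vid in s1.poses:
            np.testing.assert_array_equal(s1.poses[vid].rotation, s2.poses[vid].rotation)
            np.testing.assert_array_equal(s1.poses[vid].translation, s2.poses[vid].translation)

    def test_registered_set_grows_and_gap_shrinks(self, scene, rig24):
        """Stage monotonicity and closed-loop spread: registered views only
        grow, and the largest azimuth gap never increases across stages."""
        fe = OracleFrontEnd(scene, rig24, n_points=200, noise_sigma_px=0.0, seed=4)
        from clcfm3.sfm import compute_group_order as cgo

        groups = assign_groups(rig24, 6)
        tracks = fe.build_tracks(rig24.views)
        state = AlignState(tracks=tracks)
        cfg = AlignConfig(intrinsics_init=rig24.views[0].intrinsics)
        az = {v.view_id: v.azimuth_deg for v in rig24.views}
        prev_count = 0
        prev_gap = 360.0
        for gid in cgo(6):
            align_increment(state, groups[gid - 1].views, config=cfg)
            assert len(state.poses) >= prev_count
            covered = np.sort([az[v] for v in state.poses])
            gaps = np.diff(np.append(covered, covered[0] + 360.0))
            assert gaps.max() <= prev_gap + 1e-9
            prev_count = len(state.poses)
            prev_gap = gaps.max()
        assert prev_count == 24

    def test_noop_stage_keeps_registration(self, scene, rig8):
        """Re-feeding already-processed views adds nothing and does not
        worsen the reprojection RMSE (BA may only refine)."""
        fe = OracleFrontEnd(scene, rig8, n_points=150, noise_sigma_px=0.5, seed=5)
        cfg = AlignConfig(intrinsics_init=rig8.views[0].intrinsics)
        state = clcfm_run(rig8, G=2, front_end=fe, config=cfg)
        n, rmse = len(state.poses), state.rmse_px
        align_increment(state, rig8.views, config=cfg)
        assert len(state.poses) == n
        assert state.rmse_px <= rmse + 1e-9

    def test_single_view_first_stage_defers_bootstrap(self, scene, rig8):
        """One view cannot start a map: the stage defers it, and the view is
        registered as soon as a second one arrives."""
        fe = OracleFrontEnd(scene, rig8, n_points=100, seed=6)
        tracks = fe.build_tracks(rig8.views)
        state = AlignState(tracks=tracks)
        cfg = AlignConfig(intrinsics_init=rig8.views[0].intrinsics)
        align_increment(state, rig8.views[:1], config=cfg)
        assert state.poses == {} and len(state.pending) == 1
        align_increment(state, rig8.views[1:2], config=cfg)
        assert len(state.poses) == 2

    def test_warm_start_reuses_previous_poses(self, scene, rig24):
        """The poses entering stage s equal the poses leaving stage s-1 for
        all previously registered views (initial values really are reused)."""
        fe = OracleFrontEnd(scene, rig24, n_points=200, noise_sigma_px=0.5, seed=7)
        groups = assign_groups(rig24, 6)
        tracks = fe.build_tracks(rig24.views)
        cfg = AlignConfig(intrinsics_init=rig24.views[0].intrinsics)
        state = AlignState(tracks=tracks)
        align_increment(state, groups[0].views, config=cfg)
        snapshot = {vid: p.translation.copy() for vid, p in state.poses.items()}

        import clcfm3.sfm as sfm_mod

        seen = {}
        orig = sfm_mod.bundle_adjust

        def spy(st, cf):
            if not seen:
                seen.update({vid: p.translation.copy() for vid, p in st.poses.items()
                             if vid in snapshot})
            return orig(st, cf)

        sfm_mod.bundle_adjust, bundle_restore = spy, orig
        try:
            align_increment(state, groups[3].views, config=cfg)
        finally:
            sfm_mod.bundle_adjust = bundle_restore
        for vid, t in snapshot.items():
            np.testing.assert_array_equal(seen[vid], t)
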