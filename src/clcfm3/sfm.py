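"""Closed-loop coarse-to-fine incremental structure from motion (CLCFM).

Aligning a full-circle ring of narrow-baseline images with plain sequential
SfM accumulates drift and can fail to close the loop. CLCFM instead
decimates the ring into G groups by rotation index, so the first group
already spans the whole circle at a coarse angular spacing (the loop closes
in the very first bundle adjustment), then appends the remaining groups in
an interleaved order that keeps the processed azimuths evenly spread. Each
stage re-runs match -> register -> bundle-adjust warm-started from the
previous stage's estimates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.sparse import coo_matrix
from scipy.spatial.transform import Rotation as SciRotation

from .frontend import TrackSet
from .geometry import (
    CameraIntrinsics,
    CameraPose,
    DegenerateGeometryError,
    View,
    project_points,
    triangulate,
)
from .synthetic import RigSequence

__all__ = [
    "ViewGroup",
    "AlignState",
    "AlignConfig",
    "assign_groups",
    "compute_group_order",
    "align_increment",
    "clcfm_run",
]


@dataclass
class ViewGroup:
    group_id: int  # 1-based
    views: list[View]


@dataclass
class AlignConfig:
    """Tunables for the alignment stages."""

    min_inliers: int = 12
    huber_px: float = 2.0
    optimize_focal: bool = True
    optimize_principal_point: bool = True
    optimize_distortion: bool = True
    max_ba_iterations: int = 100
    ba_ftol: float = 1e-12
    bootstrap_target_angle_deg: float = 15.0
    bootstrap_candidates: int = 10
    intrinsics_init: Optional[CameraIntrinsics] = None


@dataclass
class AlignState:
    """Cumulative alignment estimate across CLCFM stages."""

    intrinsics: Optional[CameraIntrinsics] = None
    poses: dict[str, CameraPose] = field(default_factory=dict)
    points: dict[int, np.ndarray] = field(default_factory=dict)
    tracks: Optional[TrackSet] = None
    rmse_px: float = math.nan
    unregistered: set[str] = field(default_factory=set)
    pending: list[View] = field(default_factory=list)  # awaiting bootstrap
    stage_log: list[dict] = field(default_factory=list)
    scale_pin: Optional[tuple[str, str, float]] = None  # (vid_a, vid_b, distance)

    def registered_views(self) -> list[str]:
        return list(self.poses)

    def view_obj(self, view_id: str) -> View:
        return View(
            view_id=view_id,
            camera_row=0,
            rotation_index=0,
            azimuth_deg=0.0,
            intrinsics=self.intrinsics,
            pose=self.poses[view_id],
        )


# ---------------------------------------------------------------------------
# Grouping and ordering


def assign_groups(rig: RigSequence, G: int) -> list[ViewGroup]:
    """Partition the ring into G groups by rotation-index decimation.

    A view with rotation index r joins group ``(r mod G) + 1`` (all camera
    rows together), so group 1 covers the full circle at a spacing of
    ``G * step_deg`` and, for even G, group ``1 + G/2`` sits halfway between
    adjacent group-1 azimuths.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    if G > rig.n_rotations:
        raise ValueError(f"G={G} exceeds n_rotations={rig.n_rotations}")
    groups = [ViewGroup(group_id=g + 1, views=[]) for g in range(G)]
    for view in rig.views:
        groups[view.rotation_index % G].views.append(view)
    return groups


def compute_group_order(G: int) -> list[int]:
    """Processing order of the groups, interleaving the two halves.

    Starting from group 1, the next group is the one whose azimuths sit
    halfway between those already processed: 1, 1+ceil(G/2), 2, 2+ceil(G/2),
    ... (indices past G are skipped). For G=6 this yields [1, 4, 2, 5, 3, 6].
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    half = math.ceil(G / 2)
    order: list[int] = []
    for k in range(half):
        order.append(k + 1)
        second = k + 1 + half
        if second <= G:
            order.append(second)
    return order


# ---------------------------------------------------------------------------
# Minimal two-view / PnP building blocks


def _normalized(uv: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    xd = (uv - np.asarray(intr.principal_point)) / intr.focal_px
    return intr.undistort(xd)


def _essential_8pt(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Essential matrix from >= 8 normalized correspondences (xb' E xa = 0)."""
    A = np.column_stack(
        [
            xb[:, 0] * xa[:, 0], xb[:, 0] * xa[:, 1], xb[:, 0],
            xb[:, 1] * xa[:, 0], xb[:, 1] * xa[:, 1], xb[:, 1],
            xa[:, 0], xa[:, 1], np.ones(len(xa)),
        ]
    )
    _, _, Vt = np.linalg.svd(A)
    E = Vt[-1].reshape(3, 3)
    U, S, Vt = np.linalg.svd(E)
    s = (S[0] + S[1]) / 2
    return U @ np.diag([s, s, 0.0]) @ Vt


def _decompose_essential(E: np.ndarray, xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relative pose (R, t) of camera b w.r.t. camera a, by cheirality vote."""
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    best = None
    for R in (U @ W @ Vt, U @ W.T @ Vt):
        for t in (U[:, 2], -U[:, 2]):
            n_front = 0
            pts = _triangulate_pairs(np.eye(3), np.zeros(3), R, t, xa, xb)
            za = pts[:, 2]
            zb = (pts @ R.T + t)[:, 2]
            n_front = int(np.sum((za > 0) & (zb > 0)))
            if best is None or n_front > best[0]:
                best = (n_front, R, t)
    return best[1], best[2]


def _triangulate_pairs(Ra, ta, Rb, tb, xa, xb) -> np.ndarray:
    """Linear triangulation of normalized correspondences for two poses."""
    Pa = np.hstack([Ra, np.asarray(ta, float).reshape(3, 1)])
    Pb = np.hstack([Rb, np.asarray(tb, float).reshape(3, 1)])
    out = np.empty((len(xa), 3))
    for i in range(len(xa)):
        A = np.stack(
            [
                xa[i, 0] * Pa[2] - Pa[0],
                xa[i, 1] * Pa[2] - Pa[1],
                xb[i, 0] * Pb[2] - Pb[0],
                xb[i, 1] * Pb[2] - Pb[1],
            ]
        )
        _, _, Vt = np.linalg.svd(A)
        X = Vt[-1]
        w = X[3] if abs(X[3]) > 1e-300 else 1e-300  # point at infinity
        out[i] = X[:3] / w
    return out


def _pnp_dlt(points3d: np.ndarray, xn: np.ndarray) -> CameraPose:
    """Camera pose from >= 6 3D <-> normalized-2D correspondences (DLT)."""
    n = len(points3d)
    if n < 6:
        raise DegenerateGeometryError("PnP needs at least 6 correspondences")
    A = np.zeros((2 * n, 12))
    for i, (X, x) in enumerate(zip(points3d, xn)):
        Xh = np.append(X, 1.0)
        A[2 * i, 0:4] = Xh
        A[2 * i, 8:12] = -x[0] * Xh
        A[2 * i + 1, 4:8] = Xh
        A[2 * i + 1, 8:12] = -x[1] * Xh
    _, _, Vt = np.linalg.svd(A)
    P = Vt[-1].reshape(3, 4)
    M = P[:, :3]
    # sign: majority of points must land in front
    if np.median(points3d @ M[2] + P[2, 3]) < 0:
        P = -P
        M = -M
    U, S, Vt2 = np.linalg.svd(M)
    R = U @ Vt2
    if np.linalg.det(R) < 0:
        U[:, 2] *= -1
        R = U @ Vt2
        S = S.copy()
    scale = S.mean()
    t = P[:, 3] / scale
    return CameraPose(rotation=R, translation=t)


def _refine_pose(pose: CameraPose, intr: CameraIntrinsics, pts3d: np.ndarray, uv: np.ndarray) -> CameraPose:
    rv0 = SciRotation.from_matrix(pose.rotation).as_rotvec()
    x0 = np.concatenate([rv0, pose.translation])

    def resid(x):
        R = SciRotation.from_rotvec(x[:3]).as_matrix()
        view = View("tmp", 0, 0, 0.0, intr, CameraPose(R, x[3:]))
        proj, ok = project_points(pts3d, view)
        r = (proj - uv).ravel()
        return np.where(np.repeat(ok, 2), r, 1e3)

    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=200)
    return CameraPose(SciRotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:])


# ---------------------------------------------------------------------------
# Bundle adjustment with self-calibration


def _intrinsic_param_count(config: AlignConfig) -> int:
    n = 1 if config.optimize_focal else 0
    if config.optimize_principal_point:
        n += 2
    if config.optimize_distortion:
        n += 2
    return n


def _unpack_intrinsics(x: np.ndarray, base: CameraIntrinsics, config: AlignConfig) -> CameraIntrinsics:
    i = 0
    focal = base.focal_px
    if config.optimize_focal:
        focal = float(x[i]); i += 1
    pp = base.principal_point
    if config.optimize_principal_point:
        pp = (float(x[i]), float(x[i + 1])); i += 2
    dist = base.distortion
    if config.optimize_distortion:
        dist = (float(x[i]), float(x[i + 1])); i += 2
    w, h = base.image_size
    pp = (min(max(pp[0], 0.0), w - 1e-6), min(max(pp[1], 0.0), h - 1e-6))
    return CameraIntrinsics(max(focal, 1e-3), pp, base.image_size, dist)


def _rotvec_derivatives(rv: np.ndarray, Rm: np.ndarray) -> np.ndarray:
    """dR/dv_k for each rotation vector; output shape (n, 3, 3, 3).

    Uses the closed form dR/dv_k = (v_k [v]x + [v x ((I-R) e_k)]x) / |v|^2 R,
    falling back to [e_k]x near the identity.
    """

    def skew(w):
        return np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0.0]])

    I = np.eye(3)
    out = np.empty((len(rv), 3, 3, 3))
    for n in range(len(rv)):
        v = rv[n]
        R = Rm[n]
        th2 = float(v @ v)
        if th2 < 1e-14:
            for k in range(3):
                out[n, k] = skew(I[k])
        else:
            Vx = skew(v)
            ImR = I - R
            for k in range(3):
                out[n, k] = (v[k] * Vx + skew(np.cross(v, ImR[:, k]))) @ R / th2
    return out


def _lm_schur(
    resid_fn,
    jac_fn,
    x0: np.ndarray,
    n_cam_params: int,
    n_pts: int,
    huber_delta: float,
    max_iter: int = 100,
    ftol: float = 1e-12,
) -> np.ndarray:
    """Levenberg-Marquardt with Huber IRLS weights and a Schur complement.

    The normal equations are reduced by eliminating the 3x3 block-diagonal
    point block (the standard bundle-adjustment trick), so each iteration
    costs one sparse Jacobian, one small dense camera-system solve and one
    per-point back-substitution.
    """
    from scipy.sparse import diags

    def huber_cost(r):
        a = np.abs(r)
        return float(np.sum(np.where(a <= huber_delta, 0.5 * r * r,
                                     huber_delta * (a - 0.5 * huber_delta))))

    def weights(r):
        a = np.abs(r)
        return np.where(a <= huber_delta, 1.0, huber_delta / np.maximum(a, 1e-300))

    x = x0.copy()
    r = resid_fn(x)
    cost = huber_cost(r)
    lam = 1e-6
    nc = n_cam_params
    stall = 0
    for _ in range(max_iter):
        J = jac_fn(x).tocsc()
        w = weights(r)
        D = diags(w)
        Jc = J[:, :nc]
        Jq = J[:, nc:]
        g = J.T @ (w * r)
        gc, gq = g[:nc], g[nc:]
        A = (Jc.T @ D @ Jc).toarray()
        improved = False
        if n_pts:
            Cmat = (Jq.T @ D @ Jq).tocoo()
            Cblocks = np.zeros((n_pts, 3, 3))
            bi = Cmat.row // 3
            Cblocks[bi, Cmat.row % 3, Cmat.col - 3 * bi] = Cmat.data
            B = (Jc.T @ D @ Jq).toarray()
        for _try in range(8):
            A_d = A + lam * np.diag(np.maximum(np.diag(A), 1e-12))
            if n_pts:
                C_d = Cblocks.copy()
                idx = np.arange(3)
                C_d[:, idx, idx] += lam * np.maximum(Cblocks[:, idx, idx], 1e-12)
                try:
                    Cinv = np.linalg.inv(C_d)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                Bp = B.reshape(nc, n_pts, 3)
                BCi = np.einsum("cpi,pij->cpj", Bp, Cinv)
                S = A_d - np.einsum("cpj,dpj->cd", BCi, Bp)
                rhs = -gc + np.einsum("cpj,pj->c", BCi, gq.reshape(n_pts, 3))
                try:
                    dc = np.linalg.solve(S, rhs)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                dq = np.einsum(
                    "pij,pj->pi", Cinv,
                    (-gq.reshape(n_pts, 3) - np.einsum("cpi,c->pi", Bp, dc)),
                ).ravel()
                dx = np.concatenate([dc, dq])
            else:
                try:
                    dx = np.linalg.solve(A_d, -gc)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
            x_new = x + dx
            r_new = resid_fn(x_new)
            cost_new = huber_cost(r_new)
            if cost_new < cost:
                rel = (cost - cost_new) / max(cost, 1e-300)
                x, r, cost = x_new, r_new, cost_new
                lam = max(lam / 3.0, 1e-12)
                improved = True
                stall = stall + 1 if rel < ftol else 0
                break
            lam *= 10.0
        if not improved or stall >= 2:
            break
    return x


def bundle_adjust(state: AlignState, config: AlignConfig) -> AlignState:
    """Global BA: poses, points and shared intrinsics (self-calibration).

    The first registered view's pose is held fixed and the bootstrap-pair
    camera distance is pinned by a soft residual; together these remove the
    7-dof gauge freedom of the similarity-invariant problem. Residuals are
    pixel reprojection errors under a Huber loss; the sparse Jacobian is
    analytic.
    """
    vids = sorted(state.poses)
    if not vids or not state.points:
        return state
    tids = sorted(t for t in state.points if any(v in state.poses for v in state.tracks.obs[t]))
    vid_index = {v: i for i, v in enumerate(vids)}
    tid_index = {t: i for i, t in enumerate(tids)}

    obs_v, obs_t, obs_uv = [], [], []
    for t in tids:
        for vid, uv in state.tracks.obs[t].items():
            if vid in vid_index:
                obs_v.append(vid_index[vid])
                obs_t.append(tid_index[t])
                obs_uv.append(uv)
    obs_v = np.asarray(obs_v)
    obs_t = np.asarray(obs_t)
    obs_uv = np.asarray(obs_uv)

    n_intr = _intrinsic_param_count(config)
    n_views = len(vids)
    n_pts = len(tids)
    base_intr = state.intrinsics

    # gauge: the first registered view's pose is not a parameter at all
    p0 = state.poses[vids[0]]
    fixed_pose = np.concatenate(
        [SciRotation.from_matrix(p0.rotation).as_rotvec(), p0.translation]
    )
    n_free_views = n_views - 1

    x0 = [base_intr.focal_px] if config.optimize_focal else []
    if config.optimize_principal_point:
        x0 += list(base_intr.principal_point)
    if config.optimize_distortion:
        x0 += list(base_intr.distortion)
    for v in vids[1:]:
        p = state.poses[v]
        x0 += list(SciRotation.from_matrix(p.rotation).as_rotvec()) + list(p.translation)
    for t in tids:
        x0 += list(state.points[t])
    x0 = np.asarray(x0, float)

    pin = state.scale_pin
    pin_ok = pin is not None and pin[0] in vid_index and pin[1] in vid_index
    n_res = 2 * len(obs_uv) + (1 if pin_ok else 0)

    def unpack(x):
        intr = _unpack_intrinsics(x, base_intr, config)
        off = n_intr
        rv_free = x[off : off + 6 * n_free_views].reshape(n_free_views, 6)
        rv = np.vstack([fixed_pose[None, :], rv_free]) if n_free_views else fixed_pose[None, :]
        pts = x[off + 6 * n_free_views :].reshape(n_pts, 3)
        return intr, rv, pts

    def _forward(x):
        intr, rv, pts = unpack(x)
        Rm = SciRotation.from_rotvec(rv[:, :3]).as_matrix()
        tv = rv[:, 3:]
        P = pts[obs_t]
        pc = np.einsum("nij,nj->ni", Rm[obs_v], P) + tv[obs_v]
        return intr, Rm, tv, pts, P, pc

    def resid(x):
        intr, Rm, tv, _, _, pc = _forward(x)
        z = pc[:, 2]
        safe_z = np.where(np.abs(z) > 1e-9, z, 1e-9)
        xn = pc[:, :2] / safe_z[:, None]
        xd = intr.distort(xn)
        proj = xd * intr.focal_px + np.asarray(intr.principal_point)
        r = proj - obs_uv
        r[z <= 0] = 1e3  # behind-camera observations are heavily penalized
        out = r.ravel()
        if pin_ok:
            ia, ib, d0 = vid_index[pin[0]], vid_index[pin[1]], pin[2]
            ca = -Rm[ia].T @ tv[ia]
            cb = -Rm[ib].T @ tv[ib]
            out = np.append(out, np.linalg.norm(ca - cb) - d0)
        return out

    n_params = n_intr + 6 * n_free_views + 3 * n_pts
    n_obs = len(obs_uv)
    free_obs = obs_v > 0  # observations whose view pose is a parameter

    def jac(x):
        intr, rv_full, pts = unpack(x)
        Rm = SciRotation.from_rotvec(rv_full[:, :3]).as_matrix()
        tv = rv_full[:, 3:]
        P = pts[obs_t]
        pc = np.einsum("nij,nj->ni", Rm[obs_v], P) + tv[obs_v]
        dR = _rotvec_derivatives(rv_full[:, :3], Rm)  # (n_views, 3, 3, 3)

        f = intr.focal_px
        k1, k2 = intr.distortion
        z = pc[:, 2]
        valid = z > 0
        safe_z = np.where(np.abs(z) > 1e-9, z, 1e-9)
        iz = 1.0 / safe_z
        xn = pc[:, :2] * iz[:, None]
        r2 = np.sum(xn * xn, axis=1)
        s = 1.0 + k1 * r2 + k2 * r2 * r2
        xd = xn * s[:, None]

        # dproj/dxn = f * (s I + (2 k1 + 4 k2 r2) xn xn^T)
        g = 2.0 * k1 + 4.0 * k2 * r2
        dproj_dxn = np.zeros((n_obs, 2, 2))
        dproj_dxn[:, 0, 0] = f * (s + g * xn[:, 0] * xn[:, 0])
        dproj_dxn[:, 0, 1] = f * g * xn[:, 0] * xn[:, 1]
        dproj_dxn[:, 1, 0] = dproj_dxn[:, 0, 1]
        dproj_dxn[:, 1, 1] = f * (s + g * xn[:, 1] * xn[:, 1])
        # dxn/dpc
        dxn_dpc = np.zeros((n_obs, 2, 3))
        dxn_dpc[:, 0, 0] = iz
        dxn_dpc[:, 1, 1] = iz
        dxn_dpc[:, 0, 2] = -xn[:, 0] * iz
        dxn_dpc[:, 1, 2] = -xn[:, 1] * iz
        dproj_dpc = np.einsum("nij,njk->nik", dproj_dxn, dxn_dpc)  # (N,2,3)
        dproj_dpc[~valid] = 0.0

        rows_list, cols_list, vals_list = [], [], []
        row_pair = 2 * np.arange(n_obs)

        def add_block(col_base, block):  # block (N, 2, m); columns col_base..col_base+m-1 per obs
            m = block.shape[2]
            rr = np.repeat(row_pair, 2 * m) + np.tile(np.repeat([0, 1], m), n_obs)
            cc = np.tile(np.arange(m), 2 * n_obs) + np.repeat(col_base, 2 * m)
            rows_list.append(rr)
            cols_list.append(cc)
            vals_list.append(block.reshape(-1))

        # intrinsics
        icol = 0
        if config.optimize_focal:
            dfocal = np.where(valid[:, None], xd, 0.0)  # dproj/df
            add_block(np.full(n_obs, icol), dfocal[:, :, None])
            icol += 1
        if config.optimize_principal_point:
            dpp = np.zeros((n_obs, 2, 2))
            dpp[:, 0, 0] = 1.0
            dpp[:, 1, 1] = 1.0
            dpp[~valid] = 0.0
            add_block(np.full(n_obs, icol), dpp)
            icol += 2
        if config.optimize_distortion:
            ddist = np.zeros((n_obs, 2, 2))
            ddist[:, :, 0] = f * xn * r2[:, None]
            ddist[:, :, 1] = f * xn * (r2 * r2)[:, None]
            ddist[~valid] = 0.0
            add_block(np.full(n_obs, icol), ddist)
            icol += 2

        # poses: rotation vector then translation (fixed first view contributes 0)
        dpc_dv = np.einsum("nkij,nj->nik", dR[obs_v], P)  # (N, 3, 3): dpc/dv_k
        dproj_dv = np.einsum("nij,njk->nik", dproj_dpc, dpc_dv)
        dproj_dt = dproj_dpc.copy()  # dpc/dt = I
        pose_block = np.concatenate([dproj_dv, dproj_dt], axis=2)
        pose_block[~free_obs] = 0.0
        pose_cols = n_intr + 6 * np.maximum(obs_v - 1, 0)
        add_block(pose_cols, pose_block)

        # points: dpc/dX = R_view
        dproj_dX = np.einsum("nij,njk->nik", dproj_dpc, Rm[obs_v])
        add_block(n_intr + 6 * n_free_views + 3 * obs_t, dproj_dX)

        rows_arr = np.concatenate(rows_list)
        cols_arr = np.concatenate(cols_list)
        vals_arr = np.concatenate(vals_list)

        if pin_ok:
            ia, ib, d0 = vid_index[pin[0]], vid_index[pin[1]], pin[2]
            ca = -Rm[ia].T @ tv[ia]
            cb = -Rm[ib].T @ tv[ib]
            d = ca - cb
            nd = np.linalg.norm(d)
            u = d / (nd if nd > 1e-12 else 1.0)
            extra_r, extra_c, extra_v = [], [], []
            for sign, idx in ((1.0, ia), (-1.0, ib)):
                if idx == 0:
                    continue  # fixed view: no parameters
                # dc/dv_k = -(dR/dv_k)^T t ; dc/dt = -R^T
                for k in range(3):
                    val = sign * u @ (-(dR[idx][k].T @ tv[idx]))
                    extra_r.append(n_res - 1)
                    extra_c.append(n_intr + 6 * (idx - 1) + k)
                    extra_v.append(val)
                dt = sign * (-(Rm[idx]) @ u)  # u^T (-R^T) as column derivs
                for k in range(3):
                    extra_r.append(n_res - 1)
                    extra_c.append(n_intr + 6 * (idx - 1) + 3 + k)
                    extra_v.append(dt[k])
            if extra_r:
                rows_arr = np.concatenate([rows_arr, np.array(extra_r)])
                cols_arr = np.concatenate([cols_arr, np.array(extra_c)])
                vals_arr = np.concatenate([vals_arr, np.array(extra_v)])

        return coo_matrix((vals_arr, (rows_arr, cols_arr)), shape=(n_res, n_params)).tocsr()

    x = _lm_schur(
        resid,
        jac,
        x0,
        n_cam_params=n_intr + 6 * n_free_views,
        n_pts=n_pts,
        huber_delta=config.huber_px,
        max_iter=config.max_ba_iterations,
        ftol=config.ba_ftol,
    )
    intr, rv, pts = unpack(x)
    state.intrinsics = intr
    Rm = SciRotation.from_rotvec(rv[:, :3]).as_matrix()
    for i, vid in enumerate(vids):
        state.poses[vid] = CameraPose(Rm[i], rv[i, 3:])
    for j, t in enumerate(tids):
        state.points[t] = pts[j]
    r = resid(x)
    n_obs_res = 2 * len(obs_uv)
    state.rmse_px = float(np.sqrt(np.mean(r[:n_obs_res] ** 2))) if n_obs_res else math.nan
    return state


# ---------------------------------------------------------------------------
# Incremental alignment


def _bootstrap_pair(state: AlignState, views: list[View], config: AlignConfig) -> tuple[View, View]:
    """Pick the starting pair: most matches, median triangulation angle near
    the target (default 15 degrees), ties broken by lowest view ids."""
    by_id = {v.view_id: v for v in views}
    counts = {}
    for ida, idb in itertools.combinations(sorted(by_id), 2):
        counts[(ida, idb)] = len(state.tracks.shared(ida, idb))
    if not counts:
        raise DegenerateGeometryError("no matched pairs to bootstrap from")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    candidates = [
        (by_id[ida], by_id[idb]) for (ida, idb), c in ranked[: config.bootstrap_candidates] if c >= 8
    ]
    if not candidates:
        raise DegenerateGeometryError("fewer than 2 registrable views: no pair has enough matches")
    best = None
    intr = state.intrinsics
    for va, vb in candidates:
        shared = state.tracks.shared(va.view_id, vb.view_id)
        xa = _normalized(np.stack([state.tracks.obs[t][va.view_id] for t in shared]), intr)
        xb = _normalized(np.stack([state.tracks.obs[t][vb.view_id] for t in shared]), intr)
        try:
            E = _essential_8pt(xa, xb)
            R, tvec = _decompose_essential(E, xa, xb)
        except np.linalg.LinAlgError:
            continue
        pts = _triangulate_pairs(np.eye(3), np.zeros(3), R, tvec, xa, xb)
        ca = np.zeros(3)
        cb = -R.T @ tvec
        da = pts - ca
        db = pts - cb
        cosang = np.sum(da * db, axis=1) / (
            np.linalg.norm(da, axis=1) * np.linalg.norm(db, axis=1) + 1e-12
        )
        ang = math.degrees(np.median(np.arccos(np.clip(cosang, -1, 1))))
        score = abs(ang - config.bootstrap_target_angle_deg)
        key = (score, va.view_id, vb.view_id)
        if best is None or key < best[0]:
            best = (key, va, vb, R, tvec)
    if best is None:
        raise DegenerateGeometryError("essential-matrix bootstrap failed for all candidates")
    _, va, vb, R, tvec = best
    state.poses[va.view_id] = CameraPose(np.eye(3), np.zeros(3))
    state.poses[vb.view_id] = CameraPose(R, tvec)
    cb = -R.T @ tvec
    state.scale_pin = (va.view_id, vb.view_id, float(np.linalg.norm(cb)))
    return va, vb


def _triangulate_new_tracks(state: AlignState, min_angle_rad: float = 2e-4) -> None:
    for tid, per in state.tracks.obs.items():
        if tid in state.points:
            continue
        regs = [v for v in per if v in state.poses]
        if len(regs) < 2:
            continue
        obs = [(state.view_obj(v), tuple(per[v])) for v in regs]
        try:
            pt = triangulate(obs)
        except (DegenerateGeometryError, np.linalg.LinAlgError):
            continue
        state.points[tid] = pt.position


def _register_view(state: AlignState, view: View, config: AlignConfig) -> bool:
    per_track = [
        (t, state.tracks.obs[t][view.view_id])
        for t in state.tracks.tracks_seen_by(view.view_id)
        if t in state.points
    ]
    if len(per_track) < max(6, config.min_inliers):
        return False
    pts3d = np.stack([state.points[t] for t, _ in per_track])
    uv = np.stack([u for _, u in per_track])
    xn = _normalized(uv, state.intrinsics)
    try:
        pose = _pnp_dlt(pts3d, xn)
        pose = _refine_pose(pose, state.intrinsics, pts3d, uv)
    except (DegenerateGeometryError, np.linalg.LinAlgError):
        return False
    state.poses[view.view_id] = pose
    return True


def align_increment(
    state: AlignState,
    new_views: Sequence[View],
    config: Optional[AlignConfig] = None,
    tracks: Optional[TrackSet] = None,
) -> AlignState:
    """One CLCFM stage: register ``new_views`` and re-optimize everything.

    On the first stage the map is bootstrapped from an essential-matrix pair
    followed by incremental PnP; later stages register the new views by PnP
    against the existing tracks, warm-started from the previous state. Every
    stage finishes with a global bundle adjustment with self-calibration.
    """
    config = config or AlignConfig()
    if tracks is not None:
        state.tracks = tracks
    if state.tracks is None:
        raise ValueError("no feature tracks supplied")
    if state.intrinsics is None:
        if config.intrinsics_init is None:
            raise ValueError("config.intrinsics_init required for the first stage")
        state.intrinsics = config.intrinsics_init

    new_views = [v for v in new_views if v.view_id not in state.poses]
    first_stage = not state.poses
    if first_stage:
        pool = state.pending + list(new_views)
        if len(pool) < 2:
            # a one-view group cannot bootstrap on its own; hold it for the
            # next stage (per-view incremental scheduling, G = n_rotations)
            state.pending = pool
            state.stage_log.append(
                {"n_new": len(new_views), "n_registered": 0, "n_points": 0,
                 "rmse_px": math.nan, "deferred": True}
            )
            return state
        new_views = pool
        state.pending = []
        _bootstrap_pair(state, list(new_views), config)
        _triangulate_new_tracks(state)

    pending = [v for v in new_views if v.view_id not in state.poses]
    progress = True
    while pending and progress:
        progress = False
        still = []
        for view in pending:
            if _register_view(state, view, config):
                progress = True
                _triangulate_new_tracks(state)
            else:
                still.append(view)
        pending = still
    for view in pending:
        state.unregistered.add(view.view_id)
    for view in new_views:
        state.unregistered.discard(view.view_id) if view.view_id in state.poses else None

    bundle_adjust(state, config)
    state.stage_log.append(
        {
            "n_new": len(new_views),
            "n_registered": len(state.poses),
            "n_points": len(state.points),
            "rmse_px": state.rmse_px,
            "focal_px": state.intrinsics.focal_px,
        }
    )
    return state


def clcfm_run(
    rig: RigSequence,
    G: int = 6,
    config: Optional[AlignConfig] = None,
    front_end=None,
    tracks: Optional[TrackSet] = None,
) -> AlignState:
    """Full closed-loop coarse-to-fine alignment of a rig.

    Groups are processed in :func:`compute_group_order`; each stage calls
    :func:`align_increment`, reusing the previous stage's estimates as
    initial values.
    """
    config = config or AlignConfig()
    if config.intrinsics_init is None:
        config.intrinsics_init = rig.views[0].intrinsics
    if tracks is None:
        if front_end is None:
            raise ValueError("either a front_end or precomputed tracks are required")
        tracks = front_end.build_tracks(rig.views)
    groups = assign_groups(rig, G)
    order = compute_group_order(G)
    state = AlignState(tracks=tracks)
    for gid in order:
        align_increment(state, groups[gid - 1].views, config=config)
    if not state.poses:
        raise DegenerateGeometryError("no views could be registered")
    return state
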