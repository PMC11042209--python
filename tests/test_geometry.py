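"""Calibration, virtual-camera algebra, triangulation and alignment."""

import numpy as np
import pytest

import reachkin as rk
from reachkin.exceptions import DegenerateGeometryError, InsufficientDataError
from reachkin.synthetic import _reflect, checkerboard_scene

from _oracles import nonlinear_triangulation


def _noncoplanar_points(rng, n=24):
    return rng.uniform([-5, -5, 2], [5, 5, 12], size=(n, 3))


class TestCalibrateDLT:
    def test_noiseless_recovery_up_to_scale(self, geometry, rng):
        X = _noncoplanar_points(rng)
        x = geometry.front.project(X)
        res = rk.calibrate_dlt(rk.Correspondences(X, x))
        assert res.reprojection_error_px < 1e-6
        P_true = geometry.front.P / np.linalg.norm(geometry.front.P)
        P_est = res.camera.P / np.linalg.norm(res.camera.P)
        if np.sign(P_est[2, 3]) != np.sign(P_true[2, 3]):
            P_est = -P_est
        np.testing.assert_allclose(P_est, P_true, atol=1e-8)

    def test_mirrored_camera_detected(self, geometry, rng):
        X = _noncoplanar_points(rng)
        vc = geometry.virtual_camera("left_mirror")
        res = rk.calibrate_dlt(rk.Correspondences(X, vc.project(X), view_id="left_mirror"))
        assert res.camera.mirrored is True
        res_front = rk.calibrate_dlt(rk.Correspondences(X, geometry.front.project(X)))
        assert res_front.camera.mirrored is False

    def test_noise_keeps_reprojection_error_subpixel(self, geometry):
        errs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = _noncoplanar_points(r)
            x = geometry.front.project(X) + r.normal(0, 0.5, size=(len(X), 2))
            errs.append(rk.calibrate_dlt(rk.Correspondences(X, x)).reprojection_error_px)
        assert np.percentile(errs, 95) <= 1.0

    def test_too_few_points_rejected(self, geometry, rng):
        X = _noncoplanar_points(rng, n=5)
        with pytest.raises(InsufficientDataError):
            rk.calibrate_dlt(rk.Correspondences(X, geometry.front.project(X)))

    def test_coplanar_points_rejected(self, geometry, rng):
        X = _noncoplanar_points(rng)
        X[:, 2] = 5.0  # collapse onto one plane
        with pytest.raises(DegenerateGeometryError, match="coplanar"):
            rk.calibrate_dlt(rk.Correspondences(X, geometry.front.project(X)))


class TestMirrorCamera:
    PLANE = (np.array([-2.0, -28.0, 0.0]), np.array([np.sqrt(0.5), np.sqrt(0.5), 0.0]))

    def test_reflection_twice_restores_camera(self, geometry):
        point, normal = self.PLANE
        cam2 = rk.mirror_camera(rk.mirror_camera(geometry.front, point, normal), point, normal)
        np.testing.assert_allclose(
            cam2.P / np.linalg.norm(cam2.P),
            geometry.front.P / np.linalg.norm(geometry.front.P),
            atol=1e-12,
        )
        assert cam2.mirrored is False

    def test_point_on_mirror_plane_projects_identically(self, geometry):
        point, normal = self.PLANE
        vc = rk.mirror_camera(geometry.front, point, normal)
        in_plane = point + 3.0 * np.array([normal[1], -normal[0], 0.0]) + np.array([0, 0, 2.0])
        np.testing.assert_allclose(
            geometry.front.project(in_plane), vc.project(in_plane), atol=1e-9
        )

    def test_zero_normal_rejected(self, geometry):
        with pytest.raises(DegenerateGeometryError):
            rk.mirror_camera(geometry.front, (0, 0, 0), (0, 0, 0))

    def test_virtual_camera_matches_generator_reflection(self, geometry, rng):
        # the generator reflects points explicitly; the virtual camera
        # folds the reflection into P — both must agree everywhere
        point, normal = geometry.mirror_planes["left_mirror"]
        X = rng.uniform([-8, -5, 0], [2, 5, 8], size=(50, 3))
        via_scene = geometry.front.project(_reflect(X, point, normal))
        via_camera = geometry.virtual_camera("left_mirror").project(X)
        np.testing.assert_allclose(via_scene, via_camera, atol=1e-9)


def _helix(n=100):
    t = np.linspace(0, 4 * np.pi, n)
    return np.column_stack([np.cos(t) * 3 - 2, np.sin(t) * 3, t / 2])


class TestTriangulate:
    def _two_views(self, geometry):
        return geometry.front, geometry.virtual_camera("left_mirror")

    def test_noiseless_helix_closure(self, geometry):
        X = _helix()
        cf, cm = self._two_views(geometry)
        rec = rk.triangulate([cf.project(X), cm.project(X)], [cf, cm])
        rmse = np.sqrt(np.mean(np.sum((rec - X) ** 2, axis=1)))
        assert rmse < 1e-9

    def test_missing_view_is_local(self, geometry):
        X = _helix(20)
        cf, cm = self._two_views(geometry)
        a, b = cf.project(X), cm.project(X)
        a[7] = np.nan
        rec = rk.triangulate([a, b], [cf, cm])
        assert np.isnan(rec[7]).all()
        ok = np.delete(np.arange(20), 7)
        np.testing.assert_allclose(rec[ok], X[ok], atol=1e-8)

    def test_all_invalid_warns_and_returns_empty(self, geometry):
        cf, cm = self._two_views(geometry)
        nanobs = np.full((5, 2), np.nan)
        with pytest.warns(UserWarning, match="empty"):
            rec = rk.triangulate([nanobs, nanobs], [cf, cm])
        assert np.isnan(rec).all()

    def test_noisy_triangulation_matches_nonlinear_oracle(self, geometry):
        X = _helix(150)
        cf, cm = self._two_views(geometry)
        r = np.random.default_rng(5)
        obs = [
            cf.project(X) + r.normal(0, 0.5, (len(X), 2)),
            cm.project(X) + r.normal(0, 0.5, (len(X), 2)),
        ]
        lin = rk.triangulate(obs, [cf, cm])
        opt = nonlinear_triangulation(obs, [cf, cm])
        rmse_lin = np.sqrt(np.mean(np.sum((lin - X) ** 2, axis=1)))
        rmse_opt = np.sqrt(np.mean(np.sum((opt - X) ** 2, axis=1)))
        assert rmse_lin == pytest.approx(rmse_opt, rel=0.10)


class TestAlignment:
    def test_identity_on_nominal_frame(self, clean_palm):
        aligned, tf = rk.align_to_reference(
            clean_palm, rk.geometry.DEFAULT_REFERENCE_POINTS
        )
        assert tf.scale == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(tf.R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tf.t, 0.0, atol=1e-9)
        np.testing.assert_allclose(aligned.xyz, clean_palm.xyz, atol=1e-9, equal_nan=True)

    def test_known_rigid_offset_recovered(self, rng):
        angle = 0.4
        R = np.array(
            [
                [np.cos(angle), -np.sin(angle), 0],
                [np.sin(angle), np.cos(angle), 0],
                [0, 0, 1],
            ]
        )
        t = np.array([3.0, -2.0, 1.0])
        s = 1.2
        nominal = rk.geometry.DEFAULT_REFERENCE_POINTS
        measured = {k: s * R @ np.asarray(v, float) + t for k, v in nominal.items()}
        traj = rk.Trajectory3D(
            s * np.asarray(list(nominal.values())) @ R.T + t, fs=100.0
        )
        aligned, tf = rk.align_to_reference(traj, measured)
        np.testing.assert_allclose(aligned.xyz, list(nominal.values()), atol=1e-6)
        inv = tf.inverse()
        np.testing.assert_allclose(inv.R, R, atol=1e-9)
        np.testing.assert_allclose(inv.scale, s, atol=1e-9)

    def test_slit_to_pellet_distance_after_alignment(self):
        refs = rk.geometry.DEFAULT_REFERENCE_POINTS
        slit_mid = 0.5 * (
            np.asarray(refs["slit_left"], float) + np.asarray(refs["slit_right"], float)
        )
        assert np.linalg.norm(slit_mid - np.asarray(refs["pellet_rest"])) == pytest.approx(7.0)

    def test_collinear_references_rejected(self):
        traj = rk.Trajectory3D(np.zeros((5, 3)), fs=100.0)
        measured = {"a": (0, 0, 0), "b": (1, 0, 0), "c": (2, 0, 0)}
        with pytest.raises(DegenerateGeometryError):
            rk.align_to_reference(traj, measured, nominal=measured)

    def test_alignment_removes_calibration_gauge(self, geometry, rng):
        """Two pipelines run in different world frames must produce the
        same aligned trajectory."""
        X = _helix(40)
        refs = rk.geometry.DEFAULT_REFERENCE_POINTS
        ref_world = np.asarray(list(refs.values()), float)
        cf, cm = geometry.front, geometry.virtual_camera("left_mirror")
        results = []
        for gauge_seed in (0, 1):
            r = np.random.default_rng(gauge_seed)
            if gauge_seed == 0:
                Rg, tg, sg = np.eye(3), np.zeros(3), 1.0
            else:
                v = r.normal(size=3)
                v /= np.linalg.norm(v)
                a = 0.7
                K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
                Rg = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K
                tg, sg = np.array([5.0, -3.0, 2.0]), 0.8
            # cameras re-expressed in the gauged world frame
            G = np.eye(4)
            G[:3, :3] = sg * Rg
            G[:3, 3] = tg
            Ginv = np.linalg.inv(G)
            cams = [rk.CameraModel(cf.P @ Ginv, cf.mirrored), rk.CameraModel(cm.P @ Ginv, cm.mirrored)]
            obs = [cf.project(X), cm.project(X)]
            ref_obs = [cf.project(ref_world), cm.project(ref_world)]
            rec = rk.triangulate(obs, cams)
            ref_rec = rk.triangulate(ref_obs, cams)
            measured = {k: ref_rec[i] for i, k in enumerate(refs)}
            aligned, _ = rk.align_to_reference(
                rk.Trajectory3D(rec, fs=100.0), measured
            )
            results.append(aligned.xyz)
        np.testing.assert_allclose(results[0], results[1], atol=1e-6)


class TestCheckerboardCalibrationClosure:
    def test_corner_spacing_recovered(self):
        cfg = rk.SceneConfig(seed=3, noise_px=0.0, noise_mm=0.0)
        world, corr = checkerboard_scene(cfg, n_poses=3)
        cams = [
            rk.calibrate_dlt(corr["front"]).camera,
            rk.calibrate_dlt(corr["left_mirror"]).camera,
        ]
        rec = rk.triangulate(
            [corr["front"].image_points, corr["left_mirror"].image_points], cams
        )
        n_per = (cfg.board_rows + 1) * (cfg.board_cols + 1)
        dists = []
        for p in range(len(rec) // n_per):
            g = rec[p * n_per : (p + 1) * n_per].reshape(
                cfg.board_rows + 1, cfg.board_cols + 1, 3
            )
            dists.append(np.linalg.norm(np.diff(g, axis=0), axis=-1).ravel())
            dists.append(np.linalg.norm(np.diff(g, axis=1), axis=-1).ravel())
        mean_edge = float(np.concatenate(dists).mean())
        assert mean_edge == pytest.approx(1.0, abs=1e-6)
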