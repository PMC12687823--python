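"""Iris fitting, initial alignment, trimmed ICP and multi-view registration."""

import numpy as np
import pytest

from lensrecon.geometry import rotation_about_axis
from lensrecon.register import (
    RigidTransform,
    fit_circle_2d,
    fit_iris,
    icp_refine,
    initial_align,
)


def _circle_points(center=(1.0, 2.0, 0.0), radius=5.5, n=300, rng=None, sd=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t), np.full(n, center[2])]
    )
    if sd and rng is not None:
        pts = pts + rng.normal(0, sd, pts.shape)
    return pts


class TestIrisFit:
    def test_exact_coplanar_circle(self):
        f = fit_iris(_circle_points())
        np.testing.assert_allclose(np.abs(f.plane_normal), [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(f.circle_center, [1, 2, 0], atol=1e-9)
        assert f.circle_radius == pytest.approx(5.5, abs=1e-9)

    def test_rotated_circle_normal_recovered(self):
        R = rotation_about_axis([1, 0, 0], np.deg2rad(20))
        f = fit_iris(_circle_points() @ R.T)
        tilt = np.degrees(np.arccos(abs(f.plane_normal[2])))
        assert tilt == pytest.approx(20.0, abs=1e-9)
        assert f.circle_radius == pytest.approx(5.5, abs=1e-9)

    def test_noisy_radius_monte_carlo(self, rng):
        # radius estimate within 10 um of truth on average over 100 draws
        errs = []
        for _ in range(100):
            f = fit_iris(_circle_points(rng=rng, sd=0.010))
            errs.append(f.circle_radius - 5.5)
        assert abs(np.mean(errs)) < 0.010

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError):
            fit_iris(pts)

    def test_center_lies_on_fitted_plane(self, rng):
        R = rotation_about_axis([0.3, 1, 0], 0.4)
        f = fit_iris(_circle_points(rng=rng, sd=0.005) @ R.T)
        assert abs(f.plane_normal @ f.circle_center - f.plane_offset) < 1e-9

    def test_annulus_margin_circle_is_pupil_edge(self, rng):
        # band of iris points between pupil (r=3.5) and outer edge: the
        # fitted circle follows the inner (pupil) margin
        t = rng.uniform(0, 2 * np.pi, 3000)
        r = rng.uniform(3.5, 6.0, 3000)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(3000)])
        f = fit_iris(pts)
        assert f.circle_radius == pytest.approx(3.5, abs=0.05)


class TestInitialAlign:
    def test_already_aligned_is_identity(self):
        f = fit_iris(_circle_points(center=(0, 0, 0)))
        T = initial_align(f)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0, atol=1e-9)

    def test_known_gaze_rotation_recovered(self):
        for angle in (20.0, 30.0, 45.0):
            R = rotation_about_axis([0, 1, 0], np.deg2rad(angle))
            pts = _circle_points(center=(0, 0, 0)) @ R.T
            T = initial_align(fit_iris(pts))
            assert T.angle_deg == pytest.approx(angle, abs=0.1)
            # transformed circle centre lands on the origin
            np.testing.assert_allclose(T.apply(pts).mean(axis=0), 0, atol=1e-9)

    def test_rotation_is_proper_orthonormal(self):
        R = rotation_about_axis([1, 1, 0], 0.5)
        T = initial_align(fit_iris(_circle_points() @ R.T))
        np.testing.assert_allclose(T.rotation @ T.rotation.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-10)


class TestICP:
    def test_identical_clouds_identity(self, rng):
        cloud = rng.normal(0, 2, (500, 3))
        T, info = icp_refine(cloud, cloud)
        assert info["rms"] < 1e-12
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)

    def test_constructed_rigid_motion_recovered(self, rng):
        cloud = rng.normal(0, 2, (3000, 3))
        R = rotation_about_axis([0.3, 1, 0.1], np.deg2rad(5))
        t = np.array([0.2, -0.1, 0.05])
        T, _ = icp_refine(cloud @ R.T + t, cloud, trim_fraction=0.0)
        rec = T.apply(cloud @ R.T + t)
        assert np.abs(rec - cloud).max() < 1e-6

    def test_trimmed_mse_nonincreasing(self, young_adult, rng):
        # phantom lens surface pair with partial overlap and a perturbation
        th = np.linspace(0.1, 2.5, 80)
        ph = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        I = young_adult.lens_radial_profile(T.ravel(), P.ravel())
        pts = np.column_stack(
            [I * np.sin(T.ravel()) * np.cos(P.ravel()),
             I * np.sin(T.ravel()) * np.sin(P.ravel()),
             -I * np.cos(T.ravel())]
        )
        Rm = rotation_about_axis([0, 1, 0], np.deg2rad(2.0))
        src = pts[: len(pts) // 2] @ Rm.T + [0.05, 0.02, -0.03]
        _, info = icp_refine(src, pts, trim_fraction=0.2)
        assert np.all(np.diff(info["mse_trace"]) <= 1e-12)

    def test_no_overlap_raises(self, rng):
        a = rng.normal(0, 0.1, (100, 3))
        b = a + 100.0
        with pytest.raises(ValueError, match="overlap"):
            icp_refine(a, b)


class TestRegisterAll:
    @staticmethod
    def _synthetic_models(young_adult, angles, rng, noise_sd=0.0):
        """EyeModel3D stand-ins with exact phantom lens clouds + iris ring."""
        import pandas as pd

        from lensrecon.zernike import EyeModel3D

        eye = young_adult
        c = np.array([0, 0, eye.iris_plane_z])
        th = np.linspace(0.05, 2.6, 70)
        ph = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        I = eye.lens_radial_profile(T.ravel(), P.ravel())
        base = np.column_stack(
            [I * np.sin(T.ravel()) * np.cos(P.ravel()),
             I * np.sin(T.ravel()) * np.sin(P.ravel()),
             eye.lens_center_z - I * np.cos(T.ravel())]
        )
        half = len(base) // 2
        t_ir = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        iris = np.column_stack(
            [eye.pupil_radius * np.cos(t_ir), eye.pupil_radius * np.sin(t_ir),
             np.full(len(t_ir), eye.iris_plane_z)]
        )
        models = []
        for name, (axis, ang) in angles.items():
            R = rotation_about_axis(axis, np.deg2rad(ang)) if ang else np.eye(3)
            la = (base[:half] - c) @ R.T + c
            lp = (base[half:] - c) @ R.T + c
            ir = (iris - c) @ R.T + c
            if noise_sd:
                la = la + rng.normal(0, noise_sd, la.shape)
                lp = lp + rng.normal(0, noise_sd, lp.shape)
                ir = ir + rng.normal(0, noise_sd, ir.shape)
            rays = pd.DataFrame({"meridian_index": [0], "ascan_index": [0],
                                 "x": [0.0], "y": [0.0]})
            m = EyeModel3D(name, rays, {}, ir, distortion_state="corrected",
                           corrected_points={"LA": la, "LP": lp})
            models.append(m)
        return models

    def test_known_gaze_rotations_recovered(self, young_adult, rng):
        from lensrecon.register import register_all

        angles = {
            "on_axis": ([0, 1, 0], 0.0),
            "nasal_30": ([0, 1, 0], 30.0),
            "inferior_45": ([1, 0, 0], -45.0),
        }
        models = self._synthetic_models(young_adult, angles, rng)
        transforms, clouds = register_all(models)
        for name, (_, ang) in angles.items():
            assert transforms[name].angle_deg == pytest.approx(abs(ang), abs=0.1)
        # registered clouds coincide with the on-axis truth
        ref = np.vstack([clouds["on_axis"]["LA"], clouds["on_axis"]["LP"]])
        for name in ("nasal_30", "inferior_45"):
            cur = np.vstack([clouds[name]["LA"], clouds[name]["LP"]])
            from scipy.spatial import cKDTree

            d, _ = cKDTree(ref).query(cur)
            assert np.sqrt(np.mean(d**2)) < 0.01

    def test_single_model_equals_initial_alignment(self, young_adult, rng):
        from lensrecon.register import register_all

        models = self._synthetic_models(young_adult, {"on_axis": ([0, 1, 0], 0.0)}, rng)
        transforms, clouds = register_all(models)
        T0 = initial_align(fit_iris(models[0].iris_points))
        np.testing.assert_allclose(
            transforms["on_axis"].rotation, T0.rotation, atol=1e-12
        )

    def test_equivariance_under_common_rigid_motion(self, young_adult, rng):
        from lensrecon.register import merged_lens_cloud, register_all

        angles = {"on_axis": ([0, 1, 0], 0.0), "nasal_30": ([0, 1, 0], 30.0)}
        models = self._synthetic_models(young_adult, angles, rng)
        _, clouds0 = register_all(models)
        p0, _, _ = merged_lens_cloud(clouds0)
        # pre-rotate every input by a common motion
        M = rotation_about_axis([1, 0.2, 0], np.deg2rad(12))
        shift = np.array([0.3, -0.2, 0.5])
        for m in models:
            m.corrected_points = {k: v @ M.T + shift for k, v in m.corrected_points.items()}
            m.iris_points = m.iris_points @ M.T + shift
        _, clouds1 = register_all(models)
        p1, _, _ = merged_lens_cloud(clouds1)
        # same point ordering: residual after best-fit rigid alignment ~ 0
        a = p0 - p0.mean(axis=0)
        b = p1 - p1.mean(axis=0)
        U, _, Vt = np.linalg.svd(b.T @ a)
        R = (U @ Vt).T
        assert np.abs(b @ R.T - a).max() < 1e-6

    def test_overlap_rms_bounded_by_noise(self, young_adult, rng):
        from scipy.spatial import cKDTree

        from lensrecon.register import register_all

        sd = 0.010
        angles = {"on_axis": ([0, 1, 0], 0.0), "nasal_30": ([0, 1, 0], 30.0)}
        models = self._synthetic_models(young_adult, angles, rng, noise_sd=sd)
        _, clouds = register_all(models)
        a = np.vstack([clouds["on_axis"]["LA"], clouds["on_axis"]["LP"]])
        b = np.vstack([clouds["nasal_30"]["LA"], clouds["nasal_30"]["LP"]])
        d, _ = cKDTree(a).query(b)
        d = d[d < 0.25]
        assert np.sqrt(np.mean(d**2)) <= 2 * sd + 0.005


class TestRigidTransform:
    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_matches_sequential_apply(self, rng):
        R1 = rotation_about_axis([0, 0, 1], 0.3)
        R2 = rotation_about_axis([1, 0, 0], -0.2)
        T1 = RigidTransform(R1, np.array([1.0, 0, 0]))
        T2 = RigidTransform(R2, np.array([0, 2.0, 0]))
        p = rng.normal(size=(10, 3))
        np.testing.assert_allclose(
            T2.compose(T1).apply(p), T2.apply(T1.apply(p)), atol=1e-12
        )

    def test_circle_fit_taubin_plus_polish(self, rng):
        t = rng.uniform(0, 2 * np.pi, 50)
        xy = np.column_stack([3 + 2 * np.cos(t), -1 + 2 * np.sin(t)])
        c, r = fit_circle_2d(xy)
        np.testing.assert_allclose(c, [3, -1], atol=1e-9)
        assert r == pytest.approx(2.0, abs=1e-9)
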