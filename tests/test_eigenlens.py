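"""Polar-grid resampling, eigenlens basis algebra, restricted projection."""

import numpy as np
import pytest

from lensrecon.eigenlens import (
    EigenlensBasis,
    LensPolarGrid,
    align_lens,
    build_basis,
    cap_pair_profile,
    project,
    reconstruct,
    synthetic_training_population,
    to_polar_grid,
)


def _grid_from_profile(profile, P=100, Q=100):
    return LensPolarGrid(P=P, Q=Q, I=np.repeat(profile, Q))


@pytest.fixture(scope="module")
def training():
    grids, meta = synthetic_training_population(40, rng=0)
    return grids


@pytest.fixture(scope="module")
def basis(training):
    return build_basis(training, K=6)


class TestAlignLens:
    @staticmethod
    def _sphere_cloud(rng, center=(0, 0, 0), R=4.6, n=8000):
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = np.asarray(center) + R * u
        code = (pts[:, 2] > center[2]).astype(int)  # posterior half
        return pts, code

    def test_sphere_origin_at_center(self, rng):
        pts, code = self._sphere_cloud(rng, center=(0.5, -0.3, 2.0))
        aligned, shift = align_lens(pts, code)
        np.testing.assert_allclose(shift, [0.5, -0.3, 2.0], atol=0.05)

    def test_pre_centered_identity_shift(self, rng):
        pts, code = self._sphere_cloud(rng)
        _, shift = align_lens(pts, code)
        np.testing.assert_allclose(shift, 0, atol=0.05)

    def test_decentered_recovered_within_grid_pitch(self, rng):
        pts, code = self._sphere_cloud(rng)
        _, s0 = align_lens(pts, code)
        _, s1 = align_lens(pts + [0.3, 0, 0], code)
        assert s1[0] - s0[0] == pytest.approx(0.3, abs=0.03)


class TestToPolarGrid:
    def test_sphere_all_nodes_equal_radius(self, rng):
        u = rng.normal(size=(30000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        grid, info = to_polar_grid(4.6 * u)
        assert info["star_convexity_violations"] == 0
        assert np.nanmax(np.abs(grid.I - 4.6)) < 1e-9

    def test_ellipsoid_matches_closed_form(self):
        # dense structured sampling (finer than the grid) of an (a, a, b)
        # ellipsoid: interpolated radii match the closed form to 1e-4 mm
        a, b = 4.5, 2.0
        th = np.linspace(0, np.pi, 500)
        ph = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        I = 1.0 / np.sqrt((np.sin(T) / a) ** 2 * 1.0 + (np.cos(T) / b) ** 2)
        pts = np.column_stack(
            [(I * np.sin(T) * np.cos(P)).ravel(),
             (I * np.sin(T) * np.sin(P)).ravel(),
             (-I * np.cos(T)).ravel()]
        )
        grid, _ = to_polar_grid(pts)
        gth, _ = grid.nodes()
        I_true = 1.0 / np.sqrt((np.sin(gth) / a) ** 2 + (np.cos(gth) / b) ** 2)
        obs = grid.observed
        assert np.nanmax(np.abs(grid.I[obs] - I_true[obs])) < 1e-4

    def test_equator_gap_confined_to_band(self, young_adult):
        th = np.linspace(0, np.pi, 300)
        prof = young_adult.lens_radial_profile(th)
        keep = ~((th > 1.35) & (th < 1.75))  # carve out the equator band
        T, P = np.meshgrid(th[keep], np.linspace(0, 2 * np.pi, 200, endpoint=False),
                           indexing="ij")
        I = np.tile(prof[keep][:, None], (1, 200))
        pts = np.column_stack(
            [(I * np.sin(T) * np.cos(P)).ravel(),
             (I * np.sin(T) * np.sin(P)).ravel(),
             (-I * np.cos(T)).ravel()]
        )
        grid, _ = to_polar_grid(pts)
        gth, _ = grid.nodes()
        missing = ~grid.observed
        assert missing[(gth > 1.45) & (gth < 1.65)].all()
        assert not missing[(gth > 0.3) & (gth < 1.0)].any()


class TestBasisAlgebra:
    def test_degenerate_population_mean_and_zero_eigenvalues(self):
        g = _grid_from_profile(cap_pair_profile(np.linspace(0, np.pi, 100),
                                                9.2, 3.9, 0.42, 10.5, 6.0))
        b = build_basis([LensPolarGrid(100, 100, g.I.copy()) for _ in range(10)], K=3)
        np.testing.assert_allclose(b.mean_lens, g.I, atol=1e-12)
        assert np.abs(b.eigenvalues).max() < 1e-12

    def test_two_parameter_family_concentrates_variance(self):
        # diameter and thickness varied only: >99% variance in 2 components
        rng = np.random.default_rng(5)
        th = np.linspace(0, np.pi, 100)
        grids = []
        for _ in range(30):
            d = rng.uniform(8.5, 10.0)
            t = rng.uniform(3.4, 4.4)
            grids.append(_grid_from_profile(cap_pair_profile(th, d, t, 0.42, 0.8 * (d / 2) ** 2 / (0.42 * t), 0.8 * (d / 2) ** 2 / (0.58 * t))))
        b = build_basis(grids, K=6)
        assert b.eigenvalues[:2].sum() / b.eigenvalues.sum() > 0.99

    def test_projection_of_mean_is_zero(self, basis):
        g = LensPolarGrid(100, 100, basis.mean_lens.copy())
        np.testing.assert_allclose(project(g, basis), 0, atol=1e-10)

    def test_single_basis_vector_coefficient(self, basis):
        g = LensPolarGrid(100, 100, basis.mean_lens + 0.5 * basis.components[:, 2])
        a = project(g, basis)
        np.testing.assert_allclose(a, [0, 0, 0.5, 0, 0, 0], atol=1e-10)

    def test_project_matches_per_component_inner_products(self, basis, rng):
        I = basis.mean_lens + rng.normal(0, 0.05, basis.mean_lens.shape)
        a = project(LensPolarGrid(100, 100, I), basis)
        r = I - basis.mean_lens
        brute = np.array([basis.components[:, k] @ r for k in range(6)])
        np.testing.assert_allclose(a, brute, atol=1e-12)

    def test_project_reconstruct_idempotent(self, basis, rng):
        a = rng.normal(0, 1, 6)
        once = project(reconstruct(a, basis), basis)
        twice = project(reconstruct(once, basis), basis)
        np.testing.assert_allclose(once, a, atol=1e-10)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_pythagoras_for_out_of_span_lens(self, basis, rng):
        I = basis.mean_lens + rng.normal(0, 0.05, basis.mean_lens.shape)
        g = LensPolarGrid(100, 100, I)
        Ihat = reconstruct(project(g, basis), basis).I
        r2 = np.sum((I - basis.mean_lens) ** 2)
        fit2 = np.sum((Ihat - basis.mean_lens) ** 2)
        res2 = np.sum((I - Ihat) ** 2)
        assert r2 == pytest.approx(fit2 + res2, rel=1e-8)

    def test_heldout_error_monotone_in_k(self, training):
        th = np.linspace(0, np.pi, 100)
        g = _grid_from_profile(cap_pair_profile(th, 9.2, 3.9, 0.42, 10.5, 6.0))
        errs = []
        for K in range(1, 7):
            b = build_basis(training, K=K)
            rec = reconstruct(project(g, b), b)
            errs.append(float(np.sqrt(np.mean((rec.I - g.I) ** 2))))
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_basis_matches_sklearn_pca(self, training):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = np.stack([g.I for g in training])
        ref = sklearn.PCA(n_components=6).fit(X)
        b = build_basis(training, K=6)
        np.testing.assert_allclose(b.mean_lens, ref.mean_, atol=1e-10)
        for k in range(6):
            dot = abs(ref.components_[k] @ b.components[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_too_few_training_lenses_rejected(self, training):
        with pytest.raises(ValueError):
            build_basis(training[:4], K=6)

    def test_smoothing_attenuates_node_noise(self, basis, rng):
        # projecting iid node noise of SD sigma onto 6 of 10000 modes keeps
        # only ~sqrt(6/M) of it (x small constant)
        sigma = 0.05
        a_true = rng.normal(0, 0.5, 6)
        clean = reconstruct(a_true, basis).I
        errs = []
        for _ in range(100):
            noisy = LensPolarGrid(100, 100, clean + rng.normal(0, sigma, clean.shape))
            rec = reconstruct(project(noisy, basis), basis)
            errs.append(np.sqrt(np.mean((rec.I - clean) ** 2)))
        assert np.mean(errs) <= 3 * sigma * np.sqrt(6 / 10000)

    def test_serialization_round_trip_with_checksum(self, basis, tmp_path):
        p = tmp_path / "basis.json"
        basis.save(p)
        back = EigenlensBasis.load(p)
        np.testing.assert_allclose(back.components, basis.components, atol=1e-12)
        # tampering is detected
        txt = p.read_text().replace('"P": 100', '"P": 101', 1)
        p.write_text(txt)
        with pytest.raises(ValueError, match="checksum"):
            EigenlensBasis.load(p)


class TestRestrictedProjection:
    def test_equatorial_gap_diameter_within_2pct_of_full(self, basis):
        from lensrecon.metrics import quantify

        th = np.linspace(0, np.pi, 100)
        prof = cap_pair_profile(th, 9.2, 3.9, 0.42, 10.5, 6.0)  # the standard phantom lens
        g_full = _grid_from_profile(prof)
        full_dia = quantify(reconstruct(project(g_full, basis), basis)).DIA
        gth, _ = g_full.nodes()
        obs = ~((gth > 0.35 * np.pi) & (gth < 0.65 * np.pi))  # 30% gap
        g_gap = LensPolarGrid(100, 100, np.where(obs, g_full.I, np.nan), obs)
        gap_dia = quantify(reconstruct(project(g_gap, basis), basis)).DIA
        assert gap_dia == pytest.approx(full_dia, rel=0.02)

    def test_not_enough_observed_nodes_rejected(self, basis):
        g = LensPolarGrid(100, 100, np.full(10000, np.nan), np.zeros(10000, bool))
        with pytest.raises(ValueError):
            project(g, basis)
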