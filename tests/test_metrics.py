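"""Geometric quantification limits and the study statistics."""

import numpy as np
import pytest

from lensrecon.eigenlens import LensPolarGrid
from lensrecon.geometry import rotation_about_axis
from lensrecon.metrics import (
    bland_altman,
    coefficient_of_variation,
    compute_diameter,
    compute_surface_area,
    compute_volume,
    normality_gate,
    quantify,
    spearman,
)


def _sphere(R, P=100, Q=100):
    return LensPolarGrid(P, Q, np.full(P * Q, float(R)))


def _from_points(pts, P=100, Q=100):
    from lensrecon.eigenlens import to_polar_grid

    grid, _ = to_polar_grid(pts, P, Q)
    assert grid.observed.all()
    return grid


class TestGeometricLimits:
    @pytest.mark.parametrize("R", [1.0, 3.0, 4.6])
    def test_sphere_limits_all_within_half_percent(self, R):
        m = quantify(_sphere(R))
        assert m.DIA == pytest.approx(2 * R, rel=5e-3)
        assert m.VOL == pytest.approx(4 / 3 * np.pi * R**3, rel=5e-3)
        assert m.LSA == pytest.approx(4 * np.pi * R**2, rel=5e-3)

    def test_ellipsoid_major_axis(self):
        g = _sphere(1.0)
        th, ph = g.nodes()
        I = 1 / np.sqrt((np.sin(th) * np.cos(ph) / 5) ** 2
                        + (np.sin(th) * np.sin(ph) / 4) ** 2 + (np.cos(th) / 2) ** 2)
        m = quantify(LensPolarGrid(100, 100, I))
        assert m.DIA == pytest.approx(10.0, rel=1e-3)
        assert m.VOL == pytest.approx(4 / 3 * np.pi * 5 * 4 * 2, rel=5e-3)

    def test_two_cap_phantom_against_quadrature_oracle(self, young_adult):
        th = np.linspace(0, np.pi, 100)
        g = LensPolarGrid(100, 100, np.repeat(young_adult.lens_radial_profile(th), 100))
        m = quantify(g)
        ana = young_adult.analytic_metrics()
        assert m.DIA == pytest.approx(ana["DIA"], rel=5e-3)
        assert m.VOL == pytest.approx(ana["VOL"], rel=5e-3)
        assert m.LSA == pytest.approx(ana["LSA"], rel=1e-2)

    def test_volume_split_sums_to_total(self, young_adult):
        th = np.linspace(0, np.pi, 100)
        g = LensPolarGrid(100, 100, np.repeat(young_adult.lens_radial_profile(th), 100))
        vol, va, vp = compute_volume(g)
        assert vol == pytest.approx(va + vp, rel=1e-12)
        assert va > 0 and vp > 0 and vp > va  # posterior cap is the thicker one

    def test_rotation_invariance(self, young_adult, rng):
        # metrics of the same solid sampled in a rotated frame agree
        th = np.linspace(0, np.pi, 300)
        prof = young_adult.lens_radial_profile(th)
        T, P = np.meshgrid(th, np.linspace(0, 2 * np.pi, 300, endpoint=False), indexing="ij")
        I = np.tile(prof[:, None], (1, 300))
        pts = np.column_stack(
            [(I * np.sin(T) * np.cos(P)).ravel(),
             (I * np.sin(T) * np.sin(P)).ravel(),
             (-I * np.cos(T)).ravel()]
        )
        R = rotation_about_axis([1, 0.3, 0.1], np.deg2rad(8))
        m0 = quantify(_from_points(pts))
        m1 = quantify(_from_points(pts @ R.T))
        assert m1.VOL == pytest.approx(m0.VOL, rel=2e-3)
        assert m1.LSA == pytest.approx(m0.LSA, rel=2e-3)
        assert m1.DIA == pytest.approx(m0.DIA, rel=2e-3)

    def test_convergence_under_refinement(self, young_adult):
        ana = young_adult.analytic_metrics()
        errs_v, errs_a = [], []
        for P in (50, 100, 200):
            th = np.linspace(0, np.pi, P)
            g = LensPolarGrid(P, P, np.repeat(young_adult.lens_radial_profile(th), P))
            m = quantify(g)
            errs_v.append(abs(m.VOL - ana["VOL"]))
            errs_a.append(abs(m.LSA - ana["LSA"]))
        # at least halving of the error per doubling of the grid
        assert errs_v[1] < errs_v[0] / 2 and errs_v[2] < errs_v[1] / 2
        assert errs_a[1] < errs_a[0] / 2 and errs_a[2] < errs_a[1] / 2

    def test_incomplete_grid_rejected(self):
        g = _sphere(1.0)
        g.I[0] = np.nan
        g.observed[0] = False
        with pytest.raises(ValueError, match="closed"):
            quantify(g)


class TestCV:
    # the six repeatability triplets and their printed CVs
    @pytest.mark.parametrize(
        "values,printed",
        [
            ([9.45, 9.48, 9.55], 0.54),
            ([178, 179, 181], 0.85),
            ([8.93, 8.88, 8.94], 0.36),
            ([152, 150, 152], 0.76),
            ([135, 134, 136], 0.74),
        ],
    )
    def test_sample_sd_convention_reproduces_printed_cv(self, values, printed):
        assert round(coefficient_of_variation(values), 2) == printed

    def test_volume_triplet_truncates_to_printed_value(self):
        # (188, 190, 191): sample-SD CV = 0.8054 %, printed as 0.80 — the
        # printed inputs are themselves rounded, so agreement holds to one
        # unit in the last printed digit (and exactly under truncation)
        cv = coefficient_of_variation([188, 190, 191])
        assert np.floor(cv * 100) / 100 == 0.80
        assert abs(cv - 0.80) <= 0.01

    def test_identical_values_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_exact_permutation_p_vs_brute_force_with_ties(self, rng):
        from itertools import permutations

        from scipy import stats

        x = np.array([1, 2, 2, 3, 4, 5, 5.0])
        y = rng.normal(size=7)
        rho, p = spearman(x, y)
        # independent brute force: scipy rho over all 7! orderings of y
        rhos = []
        for perm in permutations(range(7)):
            rhos.append(stats.spearmanr(x, y[list(perm)]).statistic)
        p_brute = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert p == pytest.approx(p_brute, abs=1e-12)

    def test_large_n_uses_t_approximation(self, rng):
        from scipy import stats

        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestBlandAltman:
    def test_identical_arrays(self):
        md, lo, hi = bland_altman([1, 2, 3.0], [1, 2, 3.0])
        assert (md, lo, hi) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        md, lo, hi = bland_altman([1.5, 2.5, 3.5], [1, 2, 3.0])
        assert md == pytest.approx(0.5)
        assert lo == pytest.approx(0.5) and hi == pytest.approx(0.5)

    def test_random_fixture_against_direct_formula(self, rng):
        a = rng.normal(10, 1, 20)
        b = a + rng.normal(0.2, 0.3, 20)
        md, lo, hi = bland_altman(a, b)
        d = a - b
        assert md == pytest.approx(d.mean())
        assert hi - md == pytest.approx(1.96 * d.std(ddof=1))
        assert lo == pytest.approx(md - 1.96 * d.std(ddof=1))


class TestNormalityGate:
    def test_reference_sample_matches_independent_w(self):
        # frozen oracle: R stats::shapiro.test on this vector gives
        # W = 0.7888146949, p = 0.0067038141
        x = [148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236]
        from scipy import stats

        w = stats.shapiro(x)
        assert w.statistic == pytest.approx(0.7888146949, abs=1e-6)
        p, normal = normality_gate(x)
        assert p == pytest.approx(0.0067038141, abs=1e-6)
        assert not normal  # routes to non-parametric summaries

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_gate([1.0] * 10)

    def test_p_uniform_under_null(self, rng):
        ps = [normality_gate(rng.normal(size=50))[0] for _ in range(200)]
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 1e-3
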