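"""Gamma analysis, pass-rate summaries, radial profiles, isodose contours."""

import math

import numpy as np
import pytest

from spiralfilm import (
    GammaParams,
    PlanarDoseMap,
    gamma_brute_force,
    gamma_map,
    isodose_contours,
    pass_rate_summary,
    radial_profiles,
)
from conftest import gradient_pair


def random_pair(seed, shape=(48, 48), pitch=0.1):
    rng = np.random.default_rng(seed)
    base = rng.uniform(60, 160, shape)
    pert = base * rng.uniform(0.96, 1.04, shape)
    return (
        PlanarDoseMap(base, pitch=(pitch, pitch)),
        PlanarDoseMap(pert, pitch=(pitch, pitch)),
    )


class TestGammaAnalytic:
    def test_identity_zero_gamma(self):
        rng = np.random.default_rng(21)
        m = PlanarDoseMap(rng.uniform(10, 200, (30, 30)), pitch=(0.1, 0.1))
        r = gamma_map(m, m)
        assert np.nanmax(r.gamma) == 0.0
        assert r.pass_rate == 100.0

    def test_constant_four_percent_offset(self):
        """Constant fields leave only the dose term: gamma = 4/3 under
        3%/local normalization, pass rate 0."""
        m = PlanarDoseMap(np.full((25, 25), 100.0), pitch=(0.1, 0.1))
        c = PlanarDoseMap(np.full((25, 25), 104.0), pitch=(0.1, 0.1))
        r = gamma_map(m, c)
        np.testing.assert_allclose(r.gamma[r.mask], 4.0 / 3.0, atol=1e-12)
        assert r.pass_rate == 0.0

    def test_shifted_gradient_interior(self, shifted_gradient):
        """3 mm shift of a 1 cGy/mm gradient on a 100 cGy base: the optimum
        trades distance against dose at d = 1.5 mm, gamma = sqrt(1/2)."""
        measured, calculated = shifted_gradient
        r = gamma_map(measured, calculated, GammaParams(threshold=0.0))
        nv, nu = measured.shape
        center = r.gamma[nv // 2, nu // 2]  # pixel where D_m = 100 exactly
        assert center == pytest.approx(1 / math.sqrt(2), abs=1e-3)

    def test_scale_invariance_local(self):
        """Local normalization: scaling both maps leaves gamma unchanged."""
        m, c = random_pair(22)
        g1 = gamma_map(m, c).gamma
        m2 = PlanarDoseMap(m.values * 3.7, pitch=m.pitch)
        c2 = PlanarDoseMap(c.values * 3.7, pitch=c.pitch)
        g2 = gamma_map(m2, c2).gamma
        np.testing.assert_allclose(g1, g2, atol=1e-9)

    def test_global_normalization_constant_offset(self):
        """VanDyk mode: a 4% offset relative to a 200 cGy plane max is only
        2% of the global reference at the 100 cGy pixels."""
        vals = np.full((20, 20), 100.0)
        vals[:5] = 200.0
        m = PlanarDoseMap(vals, pitch=(0.1, 0.1))
        c = PlanarDoseMap(vals + 0.04 * 100.0, pitch=(0.1, 0.1))
        r = gamma_map(m, c, GammaParams(normalization="global", threshold=0.0))
        low = r.gamma[10:, :]
        np.testing.assert_allclose(low, 4.0 / (0.03 * 200.0), atol=1e-9)

    def test_empty_mask_raises(self):
        m = PlanarDoseMap(np.full((5, 5), np.nan), pitch=(0.1, 0.1))
        c = PlanarDoseMap(np.zeros((5, 5)), pitch=(0.1, 0.1))
        with pytest.raises(ValueError):
            gamma_map(m, c)

    def test_invalid_calc_pixels_excluded_and_counted(self):
        m = PlanarDoseMap(np.full((10, 10), 100.0), pitch=(0.1, 0.1))
        cv = np.full((10, 10), 100.0)
        cv[0, :] = np.nan
        c = PlanarDoseMap(cv, pitch=(0.1, 0.1))
        r = gamma_map(m, c)
        assert r.n_excluded_invalid_calc == 10
        assert r.n_analyzed == 90

    def test_zero_gamma_means_exact_match(self):
        m, c = random_pair(23)
        r = gamma_map(m, c)
        exact = np.isclose(m.values, c.values, rtol=0, atol=1e-12)
        zero = np.nan_to_num(r.gamma, nan=1.0) == 0.0
        assert np.all(zero[r.mask] <= exact[r.mask])


class TestGammaOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        m, c = random_pair(100 + seed, shape=(32, 32))
        g_fast = gamma_map(m, c)
        g_slow = gamma_brute_force(m, c)
        assert np.nanmax(np.abs(g_fast.gamma - g_slow.gamma)) < 1e-6
        assert g_fast.pass_rate == g_slow.pass_rate

    def test_matches_brute_force_with_shift(self):
        measured, calculated = gradient_pair(nv=11, nu=41)
        p = GammaParams(threshold=0.0)
        g_fast = gamma_map(measured, calculated, p)
        g_slow = gamma_brute_force(measured, calculated, p)
        assert np.nanmax(np.abs(g_fast.gamma - g_slow.gamma)) < 1e-6

    def test_expanding_search_finds_distant_optimum(self):
        """When doses disagree wildly, the best match may lie beyond the
        default 3*dta radius; the optimised search must still find it."""
        vals = np.full((21, 21), 100.0)
        m = PlanarDoseMap(vals, pitch=(0.1, 0.1))
        cv = np.full((21, 21), 300.0)
        cv[:, :2] = 100.0  # agreement only near the left edge
        c = PlanarDoseMap(cv, pitch=(0.1, 0.1))
        g_fast = gamma_map(m, c)
        g_slow = gamma_brute_force(m, c)
        assert np.nanmax(np.abs(g_fast.gamma - g_slow.gamma)) < 1e-6


class TestGammaMonotonicity:
    def test_pass_rate_in_dta_and_dd(self):
        m, c = random_pair(31)
        rates_dta = [
            gamma_map(m, c, GammaParams(dta=d / 10)).pass_rate
            for d in (1.0, 2.0, 3.0, 4.0)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(rates_dta, rates_dta[1:]))
        rates_dd = [
            gamma_map(m, c, GammaParams(dd=x)).pass_rate
            for x in (0.01, 0.02, 0.03, 0.05)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(rates_dd, rates_dd[1:]))

    def test_threshold_lowering_does_not_raise_pass_rate(self):
        """Low-dose pixels see larger relative differences under local
        normalization, so widening the mask cannot improve the rate."""
        measured, calculated = gradient_pair(base=60.0, slope=0.6, shift_mm=3.0)
        scaled = PlanarDoseMap(calculated.values * 1.03,
                               pitch=calculated.pitch)
        r50 = gamma_map(measured, scaled, GammaParams(threshold=0.5))
        r10 = gamma_map(measured, scaled, GammaParams(threshold=0.1))
        assert r10.pass_rate <= r50.pass_rate + 1e-12


class TestPassRateSummary:
    def test_single_value_flagged(self):
        s = pass_rate_summary([93.2])
        assert s["mean"] == s["max"] == s["min"] == 93.2
        assert s["sd"] == 0.0 and s["sd_undefined"]

    def test_equal_values(self):
        s = pass_rate_summary([90.0, 90.0, 90.0])
        assert s == {"mean": 90.0, "max": 90.0, "min": 90.0, "sd": 0.0,
                     "n": 3, "sd_undefined": False}

    def test_mean_and_sample_sd(self):
        s = pass_rate_summary([84.6, 91.2, 85.2])
        assert s["mean"] == pytest.approx(87.0, abs=1e-9)
        assert s["sd"] == pytest.approx(np.std([84.6, 91.2, 85.2], ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pass_rate_summary([])


def radial_map(n=81, pitch=0.1, sigma=1.2, peak=200.0):
    c = (n - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    r2 = ((ii - c) ** 2 + (jj - c) ** 2) * pitch**2
    return PlanarDoseMap(peak * np.exp(-r2 / (2 * sigma**2)),
                         pitch=(pitch, pitch))


class TestRadialProfiles:
    def test_thirty_profiles_at_12_degrees(self):
        m = radial_map()
        profs = radial_profiles(m, m, angle_step=12.0)
        assert len(profs) == 30
        assert [p["angle_deg"] for p in profs][:3] == [0.0, 12.0, 24.0]

    def test_rotational_symmetry(self):
        m = radial_map()
        profs = radial_profiles(m, m, angle_step=90.0)
        n = min(len(p["measured"]) for p in profs)
        ref = profs[0]["measured"][:n]
        for p in profs[1:]:
            np.testing.assert_allclose(p["measured"][:n], ref, atol=1e-6)

    def test_uniform_map_normalizes_to_one(self):
        m = PlanarDoseMap(np.full((30, 30), 120.0), pitch=(0.1, 0.1))
        for p in radial_profiles(m, m, angle_step=45.0):
            assert np.allclose(p["measured"], 1.0)
            assert np.allclose(p["calculated"], 1.0)

    def test_each_distribution_normalized_to_own_max(self):
        m = radial_map(peak=200.0)
        c = radial_map(peak=100.0)
        profs = radial_profiles(m, c, angle_step=120.0)
        for p in profs:
            np.testing.assert_allclose(p["measured"], p["calculated"],
                                       atol=1e-9)

    def test_bad_angle_step(self):
        m = radial_map()
        with pytest.raises(ValueError):
            radial_profiles(m, m, angle_step=70.0)


class TestIsodoseContours:
    def test_uniform_map_no_contours(self):
        m = PlanarDoseMap(np.full((20, 20), 50.0), pitch=(0.1, 0.1))
        assert isodose_contours(m) == []

    def test_gaussian_nested_closed_contours(self):
        m = radial_map()
        contours = isodose_contours(m, step=0.10)
        levels = sorted({c["level"] for c in contours})
        assert levels == pytest.approx([0.1 * k for k in range(1, 10)])
        # closed, and nested: enclosed area decreases with level

        def area(poly):
            x, y = poly[:, 0], poly[:, 1]
            return 0.5 * abs(np.sum(x * np.roll(y, 1) - y * np.roll(x, 1)))

        by_level = {c["level"]: area(c["vertices"]) for c in contours}
        areas = [by_level[lv] for lv in levels]
        assert all(a > b for a, b in zip(areas, areas[1:]))
        for c in contours:
            np.testing.assert_allclose(c["vertices"][0], c["vertices"][-1],
                                       atol=1e-9)

    def test_half_maximum_radius_matches_analytic(self):
        """The 50% contour of a Gaussian has radius sigma*sqrt(2 ln 2)."""
        sigma, pitch = 1.2, 0.1
        m = radial_map(sigma=sigma, pitch=pitch)
        half = [c for c in isodose_contours(m, step=0.10)
                if abs(c["level"] - 0.5) < 1e-9]
        assert len(half) == 1
        verts = half[0]["vertices"]
        center = np.array([m.u_coords().mean(), m.v_coords().mean()])
        radii = np.hypot(*(verts - center).T)
        r_analytic = sigma * math.sqrt(2 * math.log(2))
        assert abs(radii.mean() - r_analytic) < pitch
        assert np.allclose(radii, r_analytic, atol=pitch)

    def test_bad_step(self):
        with pytest.raises(ValueError):
            isodose_contours(radial_map(), step=1.5)
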