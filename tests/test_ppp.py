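"""rhohat, Berman test, ROC/AUC and the log-linear Poisson model."""

import numpy as np
import pytest

from koalasight.grid import PointPattern, Raster, StudyWindow
from koalasight.ppp import (
    berman_test,
    fit_loglinear_ppm,
    intensity_multiplier,
    rhohat,
    roc_auc,
)
from koalasight.synthetic import simulate_ipp
from koalasight.validation import alpha_for_expected_n, vertical_line_covariate


@pytest.fixture(scope="module")
def window20():
    return StudyWindow(20.0, 20.0)


@pytest.fixture(scope="module")
def line_cov20(window20):
    return vertical_line_covariate(window20, [10.0])


class TestBermanTest:
    def test_centered_sum_gives_z1_zero(self, window10, ramp_raster):
        """Twelve points with covariate sum equal to n*mu: Z1 = 0, p = 1."""
        # ramp Z = x over [0, 10]: area-weighted mean is 5.0
        x = np.array([2.5] * 6 + [7.5] * 6)
        y = np.linspace(0.5, 9.5, 12)
        res = berman_test(PointPattern(x, y, window10), ramp_raster)
        assert res.statistic_z1 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.n == 12

    def test_affine_covariate_invariance(self, window10, ramp_raster, small_pattern):
        scaled = Raster(values=3.0 * ramp_raster.values + 7.0, cellsize=1.0)
        a = berman_test(small_pattern, ramp_raster)
        b = berman_test(small_pattern, scaled)
        assert a.statistic_z1 == pytest.approx(b.statistic_z1, abs=1e-9)

    def test_negated_covariate_flips_sign(self, window10, ramp_raster, small_pattern):
        neg = Raster(values=-ramp_raster.values, cellsize=1.0)
        a = berman_test(small_pattern, ramp_raster)
        b = berman_test(small_pattern, neg)
        assert a.statistic_z1 == pytest.approx(-b.statistic_z1, abs=1e-9)

    def test_strong_negative_dependence_detected(self, window20, line_cov20):
        """beta = -3: events hug the road; Z1 strongly negative."""
        for seed in range(5):
            pat = simulate_ipp(window20, line_cov20, 2.0, -3.0, seed)
            res = berman_test(pat, line_cov20, window20)
            assert res.statistic_z1 < 0
            assert res.p_value < 1e-3

    def test_constant_covariate_rejected(self, window10, small_pattern):
        flat = Raster(values=np.full((10, 10), 2.0), cellsize=1.0)
        with pytest.raises(ValueError, match="zero variance"):
            berman_test(small_pattern, flat)


class TestRocAuc:
    def test_extreme_concentration(self, window10):
        """All events in the 10% of area nearest the feature."""
        cov = vertical_line_covariate(window10, [0.0], cellsize=0.25)
        rng = np.random.default_rng(3)
        pat = PointPattern(rng.uniform(0, 0.85, 200), rng.uniform(0, 10, 200), window10)
        roc = roc_auc(pat, cov, window10)
        assert roc.auc >= 0.95
        x, y = roc.area_fraction, roc.point_fraction
        assert y[np.searchsorted(x, 0.1)] == pytest.approx(1.0)

    def test_orientation_flip_is_exact(self, window20, line_cov20):
        pat = simulate_ipp(window20, line_cov20, 1.0, -0.5, 17)
        low = roc_auc(pat, line_cov20, window20, high_intensity_at="low").auc
        high = roc_auc(pat, line_cov20, window20, high_intensity_at="high").auc
        assert low + high == pytest.approx(1.0, abs=1e-12)

    def test_probability_form_on_toy_grid(self):
        """Exact agreement with the brute-force rank probability on 5x5."""
        w = StudyWindow(5.0, 5.0)
        rng = np.random.default_rng(11)
        vals = rng.integers(0, 4, size=(5, 5)).astype(float)  # deliberate ties
        rast = Raster(values=vals, cellsize=1.0)
        centres = [(i + 0.5, j + 0.5) for j in range(5) for i in range(5)]
        chosen = [centres[k] for k in rng.choice(25, size=7, replace=False)]
        pat = PointPattern([c[0] for c in chosen], [c[1] for c in chosen], w)
        roc = roc_auc(pat, rast, w, sample_mode="nearest")
        z_pts = rast.sample(pat.x, pat.y, mode="nearest")
        cells = vals.ravel()
        brute = np.mean(
            [
                (zp < cells).mean() + 0.5 * (zp == cells).mean()
                for zp in z_pts
            ]
        )
        assert roc.auc == pytest.approx(brute, abs=1e-12)

    def test_fractions_monotone(self, window20, line_cov20):
        pat = simulate_ipp(window20, line_cov20, 1.0, -1.0, 23)
        roc = roc_auc(pat, line_cov20, window20)
        assert (np.diff(roc.area_fraction) >= 0).all()
        assert (np.diff(roc.point_fraction) >= 0).all()
        assert roc.area_fraction[-1] == pytest.approx(1.0)
        assert roc.point_fraction[-1] == pytest.approx(1.0)


class TestRhohat:
    def test_needs_enough_points(self, window10, ramp_raster):
        pat = PointPattern([1.0] * 5, [1.0] * 5, window10)
        with pytest.raises(ValueError, match="at least 20"):
            rhohat(pat, ramp_raster)

    def test_constant_covariate_rejected(self, window10, small_pattern):
        flat = Raster(values=np.full((10, 10), 1.0), cellsize=1.0)
        with pytest.raises(ValueError, match="constant"):
            rhohat(small_pattern, flat)

    def test_mass_balance(self, window20, line_cov20):
        """integral rho_hat(z) g_hat(z) |W| dz reconstructs n within 5%."""
        pat = simulate_ipp(window20, line_cov20, 1.5, -0.8, 29)
        est = rhohat(pat, line_cov20, window20)
        mass = np.trapezoid(est.rho * est.g_density, est.z_grid) * window20.area
        assert abs(mass - pat.n) / pat.n < 0.05

    def test_band_covers_constant_under_csr(self, window20, line_cov20):
        """Homogeneous pattern: the 95% band contains n/|W| at most z."""
        fracs = []
        for seed in range(40):
            pat = simulate_ipp(window20, None, np.log(1.5), 0.0, seed)
            est = rhohat(pat, line_cov20, window20)
            inside = (est.lo <= est.baseline) & (est.baseline <= est.hi)
            fracs.append(inside.mean())
        assert np.mean(fracs) >= 0.90

    def test_concentrated_pattern_peaks_at_common_value(self, window20):
        """All events share one covariate value: rho peaks there."""
        xx, _ = window20.cell_centers()
        ramp = Raster(values=xx.astype(float), cellsize=1.0)
        rng = np.random.default_rng(2)
        pat = PointPattern(
            np.full(50, 6.5), rng.uniform(0.5, 19.5, 50), window20
        )
        est = rhohat(pat, ramp, window20)
        z0 = 6.5
        assert abs(est.z_grid[np.argmax(est.rho)] - z0) < 0.5

    def test_band_ordering_and_nonnegativity(self, window20, line_cov20):
        pat = simulate_ipp(window20, line_cov20, 1.0, -1.0, 31)
        est = rhohat(pat, line_cov20, window20)
        assert (est.rho >= 0).all()
        assert (est.lo <= est.rho).all() and (est.rho <= est.hi).all()


class TestPpmFit:
    def test_homogeneous_closed_form(self):
        """CSR on the unit window: alpha ~= log n, beta indistinguishable from 0."""
        w = StudyWindow(1.0, 1.0)
        rng = np.random.default_rng(8)
        pat = PointPattern(rng.uniform(0, 1, 100), rng.uniform(0, 1, 100), w)
        xx, _ = StudyWindow(1.0, 1.0, cellsize=0.05).cell_centers()
        ramp = Raster(values=xx.astype(float), cellsize=0.05)
        fit = fit_loglinear_ppm(pat, ramp, w, n_dummy=50)
        assert abs(fit.beta) < 2 * fit.se_beta[0]
        assert fit.intercept_alpha == pytest.approx(np.log(100), abs=0.8)

    def test_slope_recovery_single_pattern(self, window20, line_cov20):
        alpha = alpha_for_expected_n(2000, line_cov20, window20, -1.0)
        pat = simulate_ipp(window20, line_cov20, alpha, -1.0, 12)
        fit = fit_loglinear_ppm(pat, line_cov20, window20, n_dummy=120)
        assert fit.beta == pytest.approx(-1.0, abs=4 * fit.se_beta[0])
        assert fit.auc > 0.5  # road-attracted pattern is discriminable

    def test_quadrature_convergence_on_smooth_covariate(self):
        w = StudyWindow(20.0, 20.0)
        xx, _ = w.cell_centers()
        ramp = Raster(values=xx.astype(float), cellsize=1.0)
        pat = simulate_ipp(w, ramp, 1.0, -0.3, 42)
        b1 = fit_loglinear_ppm(pat, ramp, w, n_dummy=80).beta
        b2 = fit_loglinear_ppm(pat, ramp, w, n_dummy=160).beta
        assert abs(b2 - b1) < 1e-3

    def test_multi_covariate_additive(self, window20, line_cov20):
        xx, _ = window20.cell_centers()
        ramp = Raster(values=xx.astype(float), cellsize=1.0, feature_class="ramp")
        pat = simulate_ipp(window20, line_cov20, 1.0, -0.8, 3)
        fit = fit_loglinear_ppm(pat, [line_cov20, ramp], window20)
        assert fit.slope_beta.shape == (2,)
        assert fit.covariate_names == ["road", "ramp"]

    def test_too_few_points_rejected(self, window10, ramp_raster):
        pat = PointPattern([1.0, 2.0], [1.0, 2.0], window10)
        with pytest.raises(ValueError, match="at least 10"):
            fit_loglinear_ppm(pat, ramp_raster, window10)

    def test_rhohat_ppm_coherence(self, window20, line_cov20):
        """The parametric fit runs inside the nonparametric band."""
        alpha = alpha_for_expected_n(2000, line_cov20, window20, -1.0)
        pat = simulate_ipp(window20, line_cov20, alpha, -1.0, 44)
        fit = fit_loglinear_ppm(pat, line_cov20, window20, n_dummy=120)
        est = rhohat(pat, line_cov20, window20)
        z = est.z_grid
        span = z[-1] - z[0]
        central = (z >= z[0] + 0.1 * span) & (z <= z[-1] - 0.1 * span)
        lam = np.exp(fit.intercept_alpha + fit.beta * z[central])
        inside = (est.lo[central] <= lam) & (lam <= est.hi[central])
        assert inside.mean() >= 0.8


class TestIntensityMultiplier:
    def _fit_with_beta(self, beta):
        fit = object.__new__(type("F", (), {}))
        # minimal stand-in: only beta is consulted
        from koalasight.ppp import PpmFit

        return PpmFit(
            intercept_alpha=0.0, slope_beta=np.array([beta]),
            se_alpha=0.1, se_beta=np.array([0.1]), covariate_names=["z"],
            loglik=0.0, auc=0.5, n=100, n_dummy=80, converged=True,
        )

    def test_zero_slope(self):
        m, pct = intensity_multiplier(self._fit_with_beta(0.0))
        assert (m, pct) == (1.0, 0.0)

    def test_halving_slope(self):
        m, pct = intensity_multiplier(self._fit_with_beta(-np.log(2)))
        assert m == pytest.approx(0.5) and pct == pytest.approx(50.0)

    def test_two_km_composition(self):
        m, pct = intensity_multiplier(self._fit_with_beta(-np.log(2)), delta_km=2)
        assert m == pytest.approx(0.25) and pct == pytest.approx(75.0)

    def test_unit_misuse_guard(self):
        with pytest.raises(ValueError, match="sanity bound"):
            intensity_multiplier(self._fit_with_beta(-700.0))
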