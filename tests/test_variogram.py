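import numpy as np
import pytest

import coralkrige as ck
from coralkrige.grid import pairwise_haversine_km
from coralkrige.variogram import ALL_FAMILIES, MANDATORY_FAMILIES, EmpiricalVariogram

from conftest import equatorial_points


def brute_force_variogram(lats, lons, values, edges):
    """Independent all-pairs estimator used as the oracle."""
    d = pairwise_haversine_km(lats, lons)
    n = len(values)
    gamma = []
    npairs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        tot, cnt = 0.0, 0
        for a in range(n):
            for b in range(a + 1, n):
                # first bin includes its lower edge (0), others are (lo, hi]
                inside = (lo < d[a, b] <= hi) or (lo == edges[0] and d[a, b] == lo)
                if inside:
                    tot += (values[a] - values[b]) ** 2
                    cnt += 1
        gamma.append(tot / (2 * cnt) if cnt else np.nan)
        npairs.append(cnt)
    return np.array(gamma), np.array(npairs)


class TestEmpiricalVariogram:
    def test_two_points_opposite_values(self):
        lats, lons = equatorial_points([0.0, 100.0])
        emp = ck.empirical_variogram(lats, lons, [0, 1], n_lags=1, cutoff=150.0)
        assert emp.semivariance[0] == pytest.approx(0.5)
        assert emp.n_pairs[0] == 1

    def test_all_equal_values_give_zero(self):
        lats, lons = equatorial_points([0.0, 50.0, 120.0, 300.0])
        emp = ck.empirical_variogram(lats, lons, [1, 1, 1, 1], cutoff=400.0, n_lags=4)
        assert np.nansum(emp.semivariance) == 0.0

    def test_three_collinear_points_hand_example(self):
        """Points 0/1/2 km apart, values (0,1,1): gamma(1)=0.25, gamma(2)=0.5."""
        lats, lons = equatorial_points([0.0, 1.0, 2.0])
        emp = ck.empirical_variogram(lats, lons, [0, 1, 1], n_lags=2, cutoff=2.0)
        assert emp.semivariance[0] == pytest.approx(0.25, abs=1e-12)
        assert emp.n_pairs[0] == 2
        assert emp.semivariance[1] == pytest.approx(0.5, abs=1e-12)
        assert emp.n_pairs[1] == 1

    def test_coincident_points_error(self):
        with pytest.raises(ValueError, match="spread"):
            ck.empirical_variogram([1.0, 1.0], [2.0, 2.0], [0, 1])

    def test_matches_brute_force_on_200_random_points(self):
        rng = np.random.default_rng(11)
        lats = rng.uniform(-30, 30, 200)
        lons = rng.uniform(100, 160, 200)
        vals = rng.integers(0, 2, 200).astype(float)
        emp = ck.empirical_variogram(lats, lons, vals, n_lags=12)
        edges = np.linspace(0.0, emp.cutoff, 13)
        gamma, npairs = brute_force_variogram(lats, lons, vals, edges)
        assert np.array_equal(emp.n_pairs, npairs)
        occupied = npairs > 0
        assert np.allclose(emp.semivariance[occupied], gamma[occupied], atol=1e-12)

    def test_unstructured_indicator_sill_approaches_p_one_minus_p(self):
        """Spatially random binary data: large-lag semivariance ~ p(1-p)."""
        rng = np.random.default_rng(5)
        n = 2000
        lats = rng.uniform(-20, 20, n)
        lons = rng.uniform(-60, -20, n)
        p = 0.3
        vals = (rng.random(n) < p).astype(float)
        emp = ck.empirical_variogram(lats, lons, vals, n_lags=10)
        expect = p * (1 - p)
        sill_tail = np.nanmean(emp.semivariance[-3:])
        assert abs(sill_tail - expect) / expect < 0.20


class TestModelSemivariance:
    def model(self, family, **kw):
        args = {"nugget": 0.05, "partial_sill": 0.20, "range_km": 300.0}
        args.update(kw)
        return ck.VariogramModel(family, **args)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_zero_lag_is_zero(self, family):
        kappa = 1.5 if family in ("Matern", "SteinMatern") else None
        assert ck.model_semivariance(self.model(family, kappa=kappa), 0.0) == 0.0

    def test_spherical_reaches_sill_at_range(self):
        m = self.model("Spherical")
        assert ck.model_semivariance(m, 300.0) == pytest.approx(0.25)
        assert ck.model_semivariance(m, 1e6) == pytest.approx(0.25)

    def test_exponential_at_range(self):
        m = self.model("Exponential")
        assert ck.model_semivariance(m, 300.0) == pytest.approx(0.05 + 0.20 * (1 - np.exp(-1)))

    def test_gaussian_at_range(self):
        m = self.model("Gaussian")
        assert ck.model_semivariance(m, 300.0) == pytest.approx(0.05 + 0.20 * (1 - np.exp(-1)))

    def test_matern_half_kappa_equals_exponential(self):
        m_mat = self.model("Matern", kappa=0.5)
        m_exp = self.model("Exponential")
        h = np.linspace(1, 1500, 50)
        assert np.allclose(ck.model_semivariance(m_mat, h), ck.model_semivariance(m_exp, h), atol=1e-10)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_nondecreasing_in_lag(self, family):
        kappa = 1.5 if family in ("Matern", "SteinMatern") else None
        m = self.model(family, kappa=kappa)
        h = np.linspace(0.0, 1200.0, 400)
        gamma = ck.model_semivariance(m, h)
        assert np.all(np.diff(gamma) >= -1e-12)
        assert np.all(gamma >= 0.0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ck.model_semivariance(ck.VariogramModel("Cubic", 0.0, 1.0, 100.0), 10.0)


def noise_free_empirical(family, nugget=0.05, psill=0.20, range_km=300.0, kappa=None):
    h = np.linspace(20, 600, 15)
    true = ck.VariogramModel(family, nugget, psill, range_km, kappa=kappa)
    return EmpiricalVariogram(h, true(h), np.full(15, 50), cutoff=600.0)


class TestFitting:
    def test_recovers_spherical_parameters_from_exact_curve(self):
        emp = noise_free_empirical("Spherical")
        fit = ck.fit_variogram_wls(emp, "Spherical")
        assert fit.nugget == pytest.approx(0.05, abs=1e-3)
        assert fit.partial_sill == pytest.approx(0.20, abs=1e-3)
        assert fit.range_km == pytest.approx(300.0, rel=1e-3)

    def test_flat_variogram_fits_pure_nugget(self):
        h = np.linspace(20, 600, 10)
        emp = EmpiricalVariogram(h, np.full(10, 0.21), np.full(10, 40), cutoff=600.0)
        fit = ck.fit_variogram_wls(emp, "Spherical")
        assert fit.sill == pytest.approx(0.21, abs=1e-3)
        assert fit.partial_sill == pytest.approx(0.0, abs=5e-3)

    def test_supplied_initials_can_rescue_a_fit(self):
        emp = noise_free_empirical("Gaussian", range_km=80.0)
        bad = ck.fit_variogram_wls(emp, "Gaussian")
        good = ck.fit_variogram_wls(emp, "Gaussian", initial=(0.05, 0.2, 80.0))
        # the manual-initials pathway can only improve the best fit found
        assert good.rss <= bad.rss + 1e-15
        assert good.range_km == pytest.approx(80.0, rel=1e-2)

    def test_too_few_bins_error(self):
        emp = EmpiricalVariogram(np.array([10.0, 20.0]), np.array([0.1, 0.2]),
                                 np.array([5, 5]), cutoff=30.0)
        with pytest.raises(ValueError, match="lag bins"):
            ck.fit_variogram_wls(emp, "Spherical")


class TestAutofit:
    @pytest.mark.parametrize(
        "family,kappa",
        [("Spherical", None), ("Exponential", None), ("Gaussian", None), ("Matern", 1.5)],
    )
    def test_selects_generating_family_and_recovers_parameters(self, family, kappa):
        emp = noise_free_empirical(family, kappa=kappa)
        fit = ck.autofit_variogram(emp, MANDATORY_FAMILIES)
        assert fit.family == family
        assert fit.nugget == pytest.approx(0.05, rel=1e-3, abs=1e-4)
        assert fit.partial_sill == pytest.approx(0.20, rel=1e-3)
        assert fit.range_km == pytest.approx(300.0, rel=1e-3)

    def test_single_family_returned_regardless_of_quality(self):
        emp = noise_free_empirical("Gaussian")
        fit = ck.autofit_variogram(emp, ["Linear"])
        assert fit.family == "Linear"

    def test_rss_not_worse_than_any_candidate(self):
        rng = np.random.default_rng(2)
        h = np.linspace(20, 600, 15)
        g = 0.1 + 0.1 * (1 - np.exp(-h / 200)) + rng.normal(0, 0.01, 15)
        emp = EmpiricalVariogram(h, np.abs(g), np.full(15, 30), cutoff=600.0)
        fit = ck.autofit_variogram(emp, ALL_FAMILIES)
        assert fit.candidates
        assert all(fit.rss <= rss + 1e-12 for rss in fit.candidates.values())

    def test_empty_family_list_rejected(self):
        with pytest.raises(ValueError):
            ck.autofit_variogram(noise_free_empirical("Spherical"), [])

    def test_range_recovery_from_simulated_indicator_field(self):
        """Indicator data from a known spherical field: range within +/-30%.

        Median over 20 seeds at 500 points: a Gaussian random field with
        spherical covariance (range 300 km) is thresholded at its median
        to a binary indicator, then the fitted spherical range compared.
        """
        from coralkrige.variogram import _f_spherical

        true_range = 300.0
        recovered = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            lats = rng.uniform(-10, 10, n)
            lons = rng.uniform(-60, -40, n)
            d = pairwise_haversine_km(lats, lons)
            cov = 1.0 - _f_spherical(d / true_range) + 1e-8 * np.eye(n)
            field = np.linalg.cholesky(cov) @ rng.normal(size=n)
            vals = (field > 0).astype(float)
            emp = ck.empirical_variogram(lats, lons, vals, n_lags=15)
            fit = ck.autofit_variogram(emp, ["Spherical"])
            recovered.append(fit.range_km)
        med = np.median(recovered)
        assert abs(med - true_range) / true_range < 0.30
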