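import math

import numpy as np
import pytest
from scipy.signal import find_peaks

import oscspike as osc
from oscspike.theory import _abs_cos_geometric_sum


def cp(**kw):
    base = dict(w=0.5, Q=20.0, sigma_h=0.1, sigma_ou=0.05, tau_ou=0.1)
    base.update(kw)
    return osc.CanonicalParams(**base)


class TestCV:
    def test_zero_noise_zero_cv(self):
        assert osc.cv_theory(cp(sigma_h=0.0, sigma_ou=0.0)) == 0.0

    @pytest.mark.parametrize("mode", ["general", "high_q", "simplified"])
    def test_modes_agree_at_high_q_short_tau(self, mode):
        p = cp(Q=50, tau_ou=0.02)
        assert osc.cv_theory(p, mode) == pytest.approx(
            osc.cv_theory(p, "general"), rel=0.02)

    def test_local_minimum_at_integer_frequency_ratio(self):
        p = cp(sigma_h=0.2, sigma_ou=0.0, Q=50)
        cv = {w: osc.cv_theory(p.replace(w=w)) for w in (0.9, 1.0, 1.1)}
        assert cv[1.0] < cv[0.9] and cv[1.0] < cv[1.1]

    def test_overall_decline_with_frequency_ratio(self):
        p = cp(sigma_h=0.2, sigma_ou=0.0, Q=50)
        assert osc.cv_theory(p.replace(w=2.25)) < osc.cv_theory(p.replace(w=0.25))

    def test_additive_noise_contributions(self):
        p_both = cp()
        cv_h = osc.cv_theory(cp(sigma_ou=0.0))
        cv_o = osc.cv_theory(cp(sigma_h=0.0))
        assert cv_h ** 2 + cv_o ** 2 == pytest.approx(
            osc.cv_theory(p_both) ** 2, rel=1e-12)


class TestDensity:
    def test_normalised_on_default_grid(self):
        curve = osc.isi_density(None, cp())
        assert np.trapezoid(curve.values, curve.grid) == pytest.approx(1.0, abs=1e-6)
        assert np.all(curve.values >= 0)

    def test_concentrates_at_mean_in_small_noise_limit(self):
        curve = osc.isi_density(None, cp(sigma_h=1e-3, sigma_ou=1e-3))
        mode_t = curve.grid[np.argmax(curve.values)]
        assert mode_t == pytest.approx(1.0, abs=1e-3)
        sd = math.sqrt(np.trapezoid((curve.grid - 1) ** 2 * curve.values, curve.grid))
        assert sd < 2e-3

    def test_simplified_matches_full_when_narrow_band(self):
        p = cp(Q=25, sigma_h=0.1, sigma_ou=0.05, tau_ou=0.05)
        grid = osc.isi_density(None, p, mode="full").grid
        full = osc.isi_density(grid, p, mode="full").values
        simp = osc.isi_density(grid, p, mode="simplified").values
        assert np.max(np.abs(full - simp)) < 0.01 * np.max(full)

    def test_simplified_preconditions_enforced(self):
        with pytest.raises(ValueError, match="Q >= 5"):
            osc.isi_density(None, cp(Q=2.0), mode="simplified")
        with pytest.raises(ValueError, match="tau_ou <= 0.2"):
            osc.isi_density(None, cp(tau_ou=0.5), mode="simplified")

    def test_matches_simulated_isi_distribution(self, train_w04, params_w04):
        """Kolmogorov distance between theory CDF and 1e5 simulated ISIs < 0.01."""
        curve = osc.isi_density(None, params_w04, mode="full")
        emp = np.sort(train_w04.isis)
        cdf_th = curve.cdf()
        cdf_emp = np.searchsorted(emp, curve.grid, side="right") / emp.size
        assert np.max(np.abs(cdf_th - cdf_emp)) < 0.01

    def test_multimodal_at_strong_coherent_fast_oscillation(self):
        p = osc.CanonicalParams(w=2.5, Q=100, sigma_h=0.5, sigma_ou=0.01)
        curve = osc.isi_density(None, p, mode="full")
        pk, _ = find_peaks(curve.values, height=0.05 * curve.values.max(),
                           prominence=0.02 * curve.values.max())
        assert pk.size >= 2


class TestSkewness:
    def test_ou_only_positive(self):
        assert osc.skewness_theory(cp(sigma_h=0.0, sigma_ou=0.15)) > 0

    def test_near_symmetric_at_unit_frequency_ratio(self):
        assert abs(osc.skewness_theory(cp(w=1.0, Q=30, sigma_h=0.1,
                                          sigma_ou=0.02))) < 0.05

    def test_vanishes_in_small_noise_limit(self):
        assert abs(osc.skewness_theory(cp(sigma_h=1e-3, sigma_ou=1e-3))) < 0.02

    @pytest.mark.parametrize("w,sign", [(0.25, 1), (0.4, 1), (1.3, 1),
                                        (0.75, -1), (0.9, -1), (1.75, -1)])
    def test_sign_alternates_with_frequency_ratio(self, w, sign):
        """Positive skew on (n, n+1/2), negative on (n+1/2, n+1), weak OU."""
        s = osc.skewness_theory(cp(w=w, Q=50, sigma_h=0.1, sigma_ou=0.0))
        assert math.copysign(1, s) == sign

    @pytest.mark.parametrize("w", [0.75, 1.75])
    def test_strong_broadband_noise_makes_all_skews_positive(self, w):
        assert osc.skewness_theory(cp(w=w, Q=50, sigma_h=0.1, sigma_ou=0.2)) > 0


class TestNthOrderVariance:
    def test_first_order_is_squared_cv(self):
        p = cp()
        assert float(osc.nth_order_variance(1, p)) == pytest.approx(
            osc.cv_theory(p, "general") ** 2, rel=1e-12)

    def test_scc_reconstruction_identity(self):
        """rho_k rebuilt from n-th-order variances equals the closed form."""
        p = cp(sigma_h=0.15, sigma_ou=0.08)
        v = np.concatenate([[0.0],
                            osc.nth_order_variance(np.arange(1, 32, dtype=float), p)])
        rec = (v[2:] - 2 * v[1:-1] + v[:-2]) / (2 * v[1])
        direct = osc.scc_theory(np.arange(1, 31), p, mode="general")
        np.testing.assert_allclose(rec, direct, atol=1e-10)

    def test_renewal_variance_grows_linearly(self):
        p = cp(sigma_h=0.0, sigma_ou=0.1, tau_ou=0.01)
        v10 = float(osc.nth_order_variance(10, p))
        v20 = float(osc.nth_order_variance(20, p))
        assert v20 / v10 == pytest.approx(2.0, rel=5e-3)


class TestSCC:
    def test_renewal_limit_white_noise(self):
        # pure OU drive: rho_1 ~ tau/2, vanishing with the correlation time
        rho1 = {tau: abs(osc.scc_theory(1, cp(sigma_h=0.0, sigma_ou=0.1,
                                              tau_ou=tau), mode="general"))
                for tau in (0.01, 0.001)}
        assert rho1[0.01] < 0.01
        assert rho1[0.001] < 0.001
        rho = osc.scc_theory(np.arange(2, 20), cp(sigma_h=0.0, sigma_ou=0.1,
                                                  tau_ou=0.01), mode="general")
        assert np.max(np.abs(rho)) < 1e-6

    def test_bounded_by_one(self):
        for w in (0.4, 0.5, 0.8, 1.7):
            rho = osc.scc_theory(np.arange(1, 50), cp(w=w, sigma_h=0.3),
                                 mode="general")
            assert np.max(np.abs(rho)) <= 1.0

    def test_near_renewal_at_unit_frequency_ratio(self):
        p = cp(w=1.0, Q=25, sigma_h=0.15, sigma_ou=0.02)
        for mode in ("general", "simplified"):
            rho = osc.scc_theory(np.arange(1, 51), p, mode=mode)
            assert np.max(np.abs(rho)) < 0.02

    def test_matches_simulation(self, train_w04, params_w04):
        """Theory SCC within 3 Monte-Carlo SE of a 1e5-ISI simulation."""
        x = train_w04.isis
        segs = np.array_split(x, 20)
        rows = []
        for s in segs:
            c = s - s.mean()
            v = np.mean(c ** 2)
            rows.append([np.mean(c[:-k] * c[k:]) / v for k in range(1, 21)])
        rows = np.array(rows)
        se = rows.std(0, ddof=1) / math.sqrt(len(segs))
        th = osc.scc_theory(np.arange(1, 21), params_w04, mode="general")
        assert np.all(np.abs(rows.mean(0) - th) < 3 * se)

    def test_lag_validation(self):
        with pytest.raises(ValueError):
            osc.scc_theory(0, cp())
        with pytest.raises(ValueError):
            osc.scc_theory(1.5, cp())


class TestCorrelationLag:
    def test_renewal_is_zero(self):
        assert osc.correlation_lag_theory(cp(sigma_h=0.0)) == 0.0

    def test_closed_form_equals_direct_summation(self):
        p = cp(w=0.45, Q=20, sigma_h=0.2, sigma_ou=0.05)
        ks = np.arange(1, 10_001)
        direct = np.abs(osc.scc_theory(ks, p, mode="simplified")).sum()
        assert osc.correlation_lag_theory(p) == pytest.approx(direct, rel=1e-8)

    def test_increases_with_oscillation_coherence(self):
        vals = [osc.correlation_lag_theory(cp(w=0.45, Q=q, sigma_h=0.2))
                for q in (5, 10, 20, 40)]
        assert np.all(np.diff(vals) > 0)

    def test_resonant_maximum_at_half_and_minima_at_integers(self):
        p = cp(sigma_h=0.2, sigma_ou=0.05)
        tc = {w: osc.correlation_lag_theory(p.replace(w=w))
              for w in (0.45, 0.5, 0.55, 1.0, 2.0)}
        assert tc[0.5] > tc[0.45] and tc[0.5] > tc[0.55]
        assert tc[1.0] < 0.05 * tc[0.5] and tc[2.0] < 0.05 * tc[0.5]

    def test_divergence_guard(self):
        with pytest.raises(ValueError):
            _abs_cos_geometric_sum(1.0, math.pi, 0.0)


class TestPopulationTrend:
    def test_single_set_has_zero_spread(self):
        mean, sd = osc.population_trend([cp()], "Q", [10.0, 20.0])
        assert np.all(sd == 0)

    def test_identical_sets_collapse_to_single_curve(self):
        mean1, _ = osc.population_trend([cp()], "Q", [10.0, 20.0])
        mean2, sd2 = osc.population_trend([cp(), cp()], "Q", [10.0, 20.0])
        np.testing.assert_allclose(mean1, mean2)
        assert np.all(sd2 == 0)

    def test_mean_correlation_lag_increases_with_q_across_sample(self):
        sets = osc.sample_population(56, seed=77)
        grid = np.linspace(5, 30, 6)
        mean, sd = osc.population_trend(sets, "Q", grid, stat="corrlag")
        assert np.all(np.diff(mean) > 0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            osc.population_trend([], "Q", [10.0])
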