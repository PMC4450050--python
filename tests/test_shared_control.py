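import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal, norm

import cfdrshare as cf
from cfdrshare._bvn import bvn_upper, both_tails_exceed_shifted
from cfdrshare.shared_control import discretise_normal_effects, marginal_tail


class TestBvnPrimitive:
    def test_matches_scipy_mvn(self, rng):
        """Upper-quadrant probabilities agree with the mvndst integrator."""
        for _ in range(60):
            h, k = rng.normal(0, 2, 2)
            r = rng.uniform(-0.999, 0.999)
            ref = multivariate_normal.cdf([-h, -k], mean=[0, 0],
                                          cov=[[1, r], [r, 1]])
            assert float(bvn_upper(h, k, r)) == pytest.approx(ref, abs=5e-10)

    def test_far_tail_keeps_relative_accuracy(self):
        # at rho=0 the exact product is known; the algorithm must not
        # lose the ~1e-16-magnitude answer to cancellation
        got = float(bvn_upper(8.0, 2.0, 0.0))
        assert got == pytest.approx(norm.sf(8.0) * norm.sf(2.0), rel=1e-12)

    def test_degenerate_correlations(self):
        assert float(bvn_upper(0.5, 0.3, 1.0)) == pytest.approx(norm.sf(0.5))
        assert float(bvn_upper(0.5, 0.3, -1.0)) == pytest.approx(
            max(0.0, 1 - norm.cdf(0.5) - norm.cdf(0.3)))


class TestRhoShared:
    def test_no_sharing_gives_zero(self):
        d = cf.StudyPairDesign(1000, 1000, 500, 500, 0)
        assert cf.rho_shared(d) == 0.0

    def test_symmetric_full_sharing_gives_half(self):
        d = cf.StudyPairDesign(2000, 2000, 0, 0, 2000)
        assert cf.rho_shared(d) == pytest.approx(0.5)

    def test_t1d_like_design(self):
        # 6087/6088 cases, all 15171 controls shared
        d = cf.StudyPairDesign(6087, 6088, 0, 0, 15171)
        assert cf.rho_shared(d) == pytest.approx(0.2864, abs=5e-4)

    def test_genotype_simulation_oracle(self):
        """The asymptotic formula matches allele-count-level simulation."""
        d = cf.StudyPairDesign(6087, 6088, 0, 0, 15171)
        sim = cf.simulate_genotype_studies(8000, (0.05, 0.5), d, seed=5)
        emp = np.corrcoef(sim["z_i"], sim["z_j"])[0, 1]
        assert emp == pytest.approx(cf.rho_shared(d), abs=0.02)


class TestTailProb:
    def test_whole_plane(self, ):
        assert float(cf.tail_prob(0.0, 0.0, 0.5, 4.0)) == pytest.approx(1.0)

    def test_independence_factorises(self):
        z = 1.959964
        assert float(cf.tail_prob(z, z, 0.0, 0.0)) == pytest.approx(0.0025,
                                                                    rel=1e-5)

    def test_monte_carlo_oracle(self, rng):
        rho, sigma2 = 0.5, 8.0
        cov = [[1.0, rho], [rho, 1.0 + sigma2]]
        draws = rng.multivariate_normal([0, 0], cov, size=1_000_000)
        emp = np.mean((np.abs(draws[:, 0]) > 2) & (np.abs(draws[:, 1]) > 2))
        se = np.sqrt(emp * (1 - emp) / 1e6)
        got = float(cf.tail_prob(2.0, 2.0, rho, sigma2))
        assert abs(got - emp) < 3 * se

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            cf.tail_prob(1.0, 1.0, 1.0, 0.0)


class TestExpectedQuantileCum:
    def test_independence_returns_p_i_exactly(self, spec_indep):
        p = np.array([1e-30, 5e-8, 0.01, 0.5, 1.0])
        np.testing.assert_array_equal(
            cf.expected_quantile_cum(p, np.full_like(p, 0.05), spec_indep), p)

    def test_vacuous_conditioning_returns_p_i(self, spec_half):
        assert float(cf.expected_quantile_cum(0.0123, 1.0, spec_half)) == \
            pytest.approx(0.0123, rel=1e-9)

    def test_monotone_in_p_i_and_one_at_one(self, spec_half):
        p_i = np.geomspace(1e-10, 1.0, 40)
        vals = cf.expected_quantile_cum(p_i, np.full_like(p_i, 0.03), spec_half)
        assert np.all(np.diff(vals) >= -1e-12)
        assert vals[-1] == pytest.approx(1.0)

    def test_falsely_low_p_phenomenon(self, spec_half):
        """With shared controls the expected quantile exceeds the raw p."""
        for p_i in (1e-6, 1e-4, 0.01):
            for p_j in (0.001, 0.01, 0.05):
                assert float(cf.expected_quantile_cum(p_i, p_j, spec_half)) > p_i

    def test_all_null_assumption_overestimates(self, mixture):
        """Wrongly assuming every conditional SNP null inflates the quantile."""
        wrong = cf.BivariateNullSpec(
            rho=0.5, mixture=cf.NullMixture(pi0=1.0, sigma2=9.0))
        right = cf.BivariateNullSpec(rho=0.5, mixture=mixture)
        for p_j in (1e-4, 1e-3, 0.01):
            assert float(cf.expected_quantile_cum(1e-3, p_j, wrong)) > \
                float(cf.expected_quantile_cum(1e-3, p_j, right))

    def test_monte_carlo_oracle_few_configs(self, rng):
        for rho, pi0, sigma in [(0.3, 0.85, 2.0), (0.6, 0.95, 3.5)]:
            spec = cf.BivariateNullSpec(
                rho=rho, mixture=cf.NullMixture(pi0=pi0, sigma2=sigma**2))
            n = 500_000
            nn = rng.uniform(size=n) >= pi0
            eta = np.where(nn, rng.normal(0, sigma, n), 0.0)
            e1 = rng.standard_normal(n)
            e2 = rng.standard_normal(n)
            p_i = 2 * norm.sf(np.abs(e1))
            p_j = 2 * norm.sf(np.abs(eta + rho * e1
                                     + np.sqrt(1 - rho**2) * e2))
            sel = p_j <= 0.05
            emp = np.mean(p_i[sel] <= 0.01)
            se = np.sqrt(emp * (1 - emp) / sel.sum())
            got = float(cf.expected_quantile_cum(0.01, 0.05, spec))
            assert abs(got - emp) < 4 * se

    def test_out_of_range_p_rejected(self, spec_half):
        with pytest.raises(ValueError):
            cf.expected_quantile_cum(0.0, 0.5, spec_half)
        with pytest.raises(ValueError):
            cf.expected_quantile_cum(0.5, 1.5, spec_half)


class TestExpectedQuantilePoint:
    def test_independence_returns_p_i(self, spec_indep):
        assert float(cf.expected_quantile_point(0.01, 0.3, spec_indep)) == 0.01

    def test_pure_null_component_closed_form(self):
        """pi0 = 1: single conditional normal, checked against a direct
        bivariate-normal conditional computation."""
        rho = 0.5
        spec = cf.BivariateNullSpec(rho=rho,
                                    mixture=cf.NullMixture(pi0=1.0, sigma2=1.0))
        p_i, p_j = 0.01, 0.2
        z_i, z_j = cf.p_to_z(p_i), cf.p_to_z(p_j)
        sd = np.sqrt(1 - rho**2)
        expected = (norm.sf((z_i - rho * z_j) / sd)
                    + norm.cdf((-z_i - rho * z_j) / sd))
        assert float(cf.expected_quantile_point(p_i, p_j, spec)) == \
            pytest.approx(expected, rel=1e-12)

    def test_quadrature_consistency_with_cumulative(self, spec_half):
        """Integrating the point version against the conditional-p marginal
        reproduces the cumulative version on a grid."""
        pi0, s2 = spec_half.mixture.pi0, spec_half.mixture.sigma2

        def dens(z):  # z_j marginal density of the mixture
            return pi0 * norm.pdf(z) + (1 - pi0) * norm.pdf(
                z, scale=np.sqrt(1 + s2))

        for p_i in (1e-4, 1e-3, 0.01, 0.05, 0.2):
            for p_j in (0.001, 0.01, 0.05, 0.3, 0.9):
                zj = norm.isf(p_j / 2)
                num = quad(lambda z: float(cf.expected_quantile_point(
                    p_i, 2 * norm.sf(z), spec_half)) * dens(z),
                    zj, zj + 12, limit=200)[0]
                den = quad(dens, zj, zj + 12, limit=200)[0]
                cum = float(cf.expected_quantile_cum(p_i, p_j, spec_half))
                assert num / den == pytest.approx(cum, abs=1e-4)

    def test_invalid_p_j_rejected(self, spec_half):
        with pytest.raises(ValueError):
            cf.expected_quantile_point(0.01, 0.0, spec_half)


class TestExpectedQuantileNumeric:
    def test_matches_closed_form_for_normal_effects(self, spec_half):
        grid, dens = discretise_normal_effects(3.0, n=801)
        for p_i, p_j in [(1e-4, 0.01), (0.01, 0.05), (0.2, 0.5)]:
            got = cf.expected_quantile_cum_numeric(
                p_i, p_j, 0.5, grid, dens, point_mass0=0.9)
            ref = float(cf.expected_quantile_cum(p_i, p_j, spec_half))
            assert float(got) == pytest.approx(ref, abs=1e-3)

    def test_point_mass_only_reduces_to_pure_null(self):
        spec1 = cf.BivariateNullSpec(rho=0.4,
                                     mixture=cf.NullMixture(pi0=1.0, sigma2=1.0))
        got = cf.expected_quantile_cum_numeric(
            0.01, 0.05, 0.4, np.array([0.0]), np.array([1.0]), point_mass0=1.0)
        assert float(got) == pytest.approx(
            float(cf.expected_quantile_cum(0.01, 0.05, spec1)), rel=1e-10)

    def test_normal_assumption_robust_to_heavy_tailed_effects(self):
        """With markedly heavy-tailed true effects (scaled t with 3 df),
        the normal-mixture approximation fitted by EM to the observed Z
        scores stays within a modest relative error of the exact
        heavy-tailed expected quantile, even deep in the tail."""
        from scipy.stats import t as t_dist

        rng = np.random.default_rng(4)
        scale, n = 2.0, 200_000
        nn = rng.uniform(size=n) >= 0.9
        eta = np.where(nn, scale * rng.standard_t(3, size=n), 0.0)
        fit = cf.fit_em(eta + rng.standard_normal(n))
        spec_norm = cf.BivariateNullSpec(rho=0.5, mixture=fit)
        grid = np.linspace(-40, 40, 2001)
        dens_t = t_dist.pdf(grid / scale, 3) / scale
        for p_i in (1e-6, 1e-5, 1e-4):
            for p_j in (1e-3, 0.01):
                exact = float(cf.expected_quantile_cum_numeric(
                    p_i, p_j, 0.5, grid, dens_t, point_mass0=0.9))
                approx = float(cf.expected_quantile_cum(p_i, p_j, spec_norm))
                assert approx == pytest.approx(exact, rel=0.25)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            cf.expected_quantile_cum_numeric(
                0.01, 0.05, 0.3, np.array([0.0, 1.0]), np.array([1.0, -1.0]))


class TestMarginalTail:
    def test_matches_scaled_normal(self):
        assert float(marginal_tail(2.0, 3.0)) == pytest.approx(
            2 * norm.sf(1.0), rel=1e-12)


class TestShiftedTails:
    def test_shifted_tail_matches_monte_carlo(self, rng):
        r, eta = 0.6, 1.5
        z = rng.multivariate_normal([0, eta], [[1, r], [r, 1]], size=500_000)
        emp = np.mean((np.abs(z[:, 0]) > 1.0) & (np.abs(z[:, 1]) > 0.8))
        got = float(both_tails_exceed_shifted(1.0, 0.8, r, eta))
        assert got == pytest.approx(emp, abs=4 * np.sqrt(emp * (1 - emp) / 5e5))
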