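import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from phylonb.model import (
    ParameterState,
    UnconstrainedDensity,
    dispersion_trend_location,
    joint_log_density,
    linear_predictor,
    nb_log_pmf,
)


def _random_density(seed, n=25, j=7, centered=True):
    rng = np.random.default_rng(seed)
    fam = rng.integers(0, 2, j)
    fam[:2] = [0, 1]
    x = rng.normal(0, 1, n)
    Y = rng.poisson(6, (n, j))
    z = rng.integers(1, 50, n)
    return UnconstrainedDensity(Y, x, z, fam, centered=centered), Y, x, z, fam


class TestNbLogPmf:
    def test_zero_count_closed_form(self):
        # P(0) = (phi/(phi+mu))^phi; mu=phi=1 gives 1/2
        assert nb_log_pmf(0, 1.0, 1.0) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_matches_gamma_poisson_mixture(self):
        # frozen value from numerically integrating the gamma-Poisson mixture
        assert nb_log_pmf(2, 3.0, 5.0) == pytest.approx(-1.60362645114992, abs=1e-9)

    def test_poisson_limit_at_large_phi(self):
        want = stats.poisson.logpmf(4, 2.0)
        assert nb_log_pmf(4, 2.0, 1e8) == pytest.approx(want, abs=1e-4)

    @pytest.mark.parametrize("mu,phi", [(0.5, 2.0), (7.3, 0.4), (20.0, 5.0)])
    def test_normalizes_to_one(self, mu, phi):
        ymax = int(mu + 40 * math.sqrt(mu + mu * mu / phi)) + 60
        total = np.exp(nb_log_pmf(np.arange(ymax), mu, phi)).sum()
        assert abs(1.0 - total) < 1e-6

    def test_moments_match_parameterization(self):
        # Var = mu + mu^2/phi within Monte-Carlo error
        mu, phi, n = 5.0, 2.0, 10**5
        rng = np.random.default_rng(123)
        draws = rng.negative_binomial(phi, phi / (phi + mu), size=n)
        var_expected = mu + mu * mu / phi
        # SE of the sample variance via the fourth moment
        m4 = np.mean((draws - draws.mean()) ** 4)
        se = math.sqrt((m4 - (n - 3) / (n - 1) * draws.var() ** 2) / n)
        assert abs(draws.var() - var_expected) < 3 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_log_pmf(1, -1.0, 1.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1, 1.0, 0.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1.5, 1.0, 1.0)


class TestLinearPredictor:
    def test_direct_evaluation(self):
        assert linear_predictor(2.0, 0.5, 1.0, 1.0) == pytest.approx(math.exp(2.5))

    def test_null_slope_reduces_to_scaled_intercept(self):
        for x in (-3.0, 0.0, 9.9):
            assert linear_predictor(1.2, 0.0, x, 7.0) == pytest.approx(math.exp(1.2) * 7.0)

    def test_offset_passthrough(self):
        assert linear_predictor(0.0, 0.0, 0.0, 100.0) == pytest.approx(100.0)

    def test_nonpositive_offset_rejected(self):
        with pytest.raises(ValueError):
            linear_predictor(0.0, 0.0, 0.0, 0.0)


class TestDispersionTrend:
    @pytest.mark.parametrize(
        "a1,a0,mean,want",
        [(0.0, 0.0, 17.3, 0.0), (0.1, -1.0, 20.0, 1.0), (1.0, 0.0, 3.7, 3.7)],
    )
    def test_linear_evaluation(self, a1, a0, mean, want):
        assert dispersion_trend_location(mean, a1, a0) == pytest.approx(want)


def _state_for(density, rng, scale=0.3):
    return rng.normal(0, scale, density.dim)


class TestJointDensity:
    def test_single_cell_hand_sum(self):
        """One OTU, one subject, zero count: sum the model's seven prior
        and likelihood blocks independently with scipy distributions."""
        Y = np.array([[0]])
        x = np.array([0.4])
        z = np.array([2.0])
        fam = np.array([0])
        st = ParameterState(
            mu_alpha=0.3, mu_beta=-0.2, sigma_alpha=1.1, sigma_beta=0.9,
            omega=-0.5, a1=0.2, a0=-0.1, sigma_phi=0.8,
            mu_alpha_fam=np.array([0.5]), mu_beta_fam=np.array([-0.4]),
            sigma_alpha_fam=np.array([0.7]), sigma_beta_fam=np.array([1.3]),
            alpha=np.array([0.6]), beta=np.array([-0.3]), phi=np.array([1.4]),
        )
        mu = math.exp(0.6 + 0.4 * -0.3 + math.log(2.0))
        want = stats.nbinom.logpmf(0, 1.4, 1.4 / (1.4 + mu))
        cov = np.array(
            [
                [0.7**2, -0.5 * 0.7 * 1.3],
                [-0.5 * 0.7 * 1.3, 1.3**2],
            ]
        )
        want += stats.multivariate_normal.logpdf([0.6, -0.3], [0.5, -0.4], cov)
        want += stats.norm.logpdf(0.5, 0.3, 1.1) + stats.norm.logpdf(-0.4, -0.2, 0.9)
        want += stats.norm.logpdf(0.3) + stats.norm.logpdf(-0.2)
        want += stats.expon.logpdf(1.1) + stats.expon.logpdf(0.9)
        want += stats.expon.logpdf(0.7) + stats.expon.logpdf(1.3)
        want += stats.uniform.logpdf(-0.5, -1, 2)
        mu_phi = 0.2 * mu + -0.1
        want += stats.lognorm.logpdf(1.4, s=0.8, scale=math.exp(mu_phi))
        want += stats.norm.logpdf(0.2) + stats.norm.logpdf(-0.1)
        want += stats.expon.logpdf(0.8)
        got = joint_log_density(st, Y, x, np.log(z), fam)
        assert got == pytest.approx(want, abs=1e-10)

    def test_likelihood_additivity_under_subject_duplication(self):
        d, Y, x, z, fam = _random_density(5)
        st = d.unpack(np.random.default_rng(0).normal(0, 0.2, d.dim))
        base = joint_log_density(st, Y, x, np.log(z), fam)
        doubled = joint_log_density(
            st, np.vstack([Y, Y]), np.concatenate([x, x]),
            np.log(np.concatenate([z, z])), fam,
        )
        # doubling the data doubles the likelihood term exactly while the
        # priors (including the trend location, which averages mu over
        # subjects) are unchanged, so the difference is one likelihood
        mu = np.exp(st.alpha[None, :] + x[:, None] * st.beta[None, :] + np.log(z)[:, None])
        lik = float(np.sum(nb_log_pmf(Y, mu, st.phi[None, :])))
        # the dispersion-trend location depends on the average mu and is
        # unchanged by duplicating every subject
        assert doubled - base == pytest.approx(lik, rel=1e-10)

    @pytest.mark.parametrize("centered", [True, False])
    def test_unconstrained_matches_natural_plus_jacobian(self, centered):
        d, Y, x, z, fam = _random_density(11, centered=centered)
        rng = np.random.default_rng(3)
        for _ in range(5):
            th = _state_for(d, rng)
            lp, _ = d.logp_grad(th)
            want = joint_log_density(d.unpack(th), Y, x, np.log(z), fam)
            assert lp == pytest.approx(want + d.log_jacobian(th), rel=1e-10)

    @pytest.mark.parametrize("centered", [True, False])
    def test_parameterizations_agree_on_natural_density(self, centered):
        """pack/unpack round-trips and both coordinate systems describe
        the same distribution over natural parameters."""
        d, Y, x, z, fam = _random_density(2, centered=centered)
        other = UnconstrainedDensity(Y, x, z, fam, centered=not centered)
        rng = np.random.default_rng(8)
        th = _state_for(d, rng)
        st = d.unpack(th)
        np.testing.assert_allclose(d.pack(st), th, atol=1e-9)
        th2 = other.pack(st)
        st2 = other.unpack(th2)
        np.testing.assert_allclose(st2.beta, st.beta, atol=1e-9)
        lp1 = joint_log_density(st, Y, x, np.log(z), fam)
        lp2 = joint_log_density(st2, Y, x, np.log(z), fam)
        assert lp1 == pytest.approx(lp2, rel=1e-12)

    @pytest.mark.parametrize("centered", [True, False])
    def test_gradient_matches_finite_differences(self, centered):
        d, *_ = _random_density(17, centered=centered)
        rng = np.random.default_rng(42)
        eps = 1e-6
        for _ in range(10):
            th = _state_for(d, rng)
            _, g = d.logp_grad(th)
            fd = np.empty(d.dim)
            for i in range(d.dim):
                tp = th.copy()
                tp[i] += eps
                tm = th.copy()
                tm[i] -= eps
                fd[i] = (d.logp(tp) - d.logp(tm)) / (2 * eps)
            rel = np.abs(g - fd) / np.maximum(1e-6, np.abs(g) + np.abs(fd))
            assert rel.max() < 1e-4

    def test_invalid_state_rejected(self):
        d, Y, x, z, fam = _random_density(1)
        st = d.unpack(np.zeros(d.dim))
        st.omega = 1.5
        with pytest.raises(ValueError):
            joint_log_density(st, Y, x, np.log(z), fam)

    def test_nonfinite_vector_gets_zero_weight(self):
        d, *_ = _random_density(1)
        lp, g = d.logp_grad(np.full(d.dim, np.nan))
        assert lp == -math.inf and np.all(g == 0)
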