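"""NB likelihood, horseshoe prior, joint density and its analytic gradient."""

import numpy as np
import pytest
from scipy import special, stats

from sigtrend.model import (
    DELTA_SUM_SD,
    GlobalParams,
    HorseshoeConfig,
    ModelState,
    UnconstrainedModel,
    expected_abundance,
    horseshoe_log_prior,
    joint_log_density,
    nb_log_pmf,
    regularized_scales,
    _gamma_logpdf,
    _half_normal_logpdf,
    _half_student_t_logpdf,
    _normal_logpdf,
    _scaled_inv_chi2_logpdf,
)
from sigtrend.sigmoid import GeneCurveParams, InvalidArgumentError, gla


def toy_state(rng, G=5, T=4, R=2):
    genes = [
        GeneCurveParams(
            y0=float(rng.uniform(5, 50)),
            beta=rng.normal(0, 0.5, size=R),
            eta=float(rng.normal()),
        )
        for _ in range(G)
    ]
    glob = GlobalParams(
        delta=rng.normal(0, 0.01, size=T),
        omega=float(rng.uniform(1, 10)),
        sigma=np.abs(rng.normal(1, 0.2, size=R - 1)),
        gamma1=float(rng.uniform(0.5, 2)),
        gamma2=float(rng.uniform(0.01, 0.1)),
        hs_global_scale=float(rng.uniform(0.05, 0.5)),
        hs_local_scales=np.abs(rng.standard_cauchy(G)) + 0.01,
        hs_slab=float(rng.uniform(0.3, 1.0)),
    )
    return ModelState(globals=glob, genes=genes)


def toy_data(rng, G=5, T=4, R=2):
    X = np.column_stack([np.linspace(-1.5, 1.5, T)] + [rng.normal(size=T) for _ in range(R - 1)])
    Y = rng.poisson(30, size=(G, T))
    return Y, X


class TestNbLogPmf:
    def test_zero_count_closed_form(self):
        # at y=0 the pmf reduces to (omega/(omega+mu))^omega
        assert nb_log_pmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_normalisation(self):
        y = np.arange(0, 10001)
        total = np.exp(nb_log_pmf(y, 5.0, 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy_parameterisation(self):
        # variance mu + mu^2/omega corresponds to nbinom(n=omega, p=omega/(omega+mu))
        y = np.arange(0, 50)
        mu, omega = 7.3, 2.6
        ours = nb_log_pmf(y, mu, omega)
        ref = stats.nbinom.logpmf(y, omega, omega / (omega + mu))
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_large_omega_poisson_limit(self):
        y = np.arange(0, 21)
        ours = nb_log_pmf(y, 3.0, 1e8)
        pois = stats.poisson.logpmf(y, 3.0)
        assert np.max(np.abs(ours - pois)) < 1e-4

    def test_rejects_invalid(self):
        with pytest.raises(InvalidArgumentError):
            nb_log_pmf(-1, 1.0, 1.0)
        with pytest.raises(InvalidArgumentError):
            nb_log_pmf(1.5, 1.0, 1.0)
        with pytest.raises(InvalidArgumentError):
            nb_log_pmf(1, -1.0, 1.0)


class TestExpectedAbundance:
    def test_flat_genes_give_constant_columns(self):
        rng = np.random.default_rng(0)
        state = toy_state(rng)
        for g in state.genes:
            object.__setattr__(g, "beta", np.zeros_like(g.beta))
        state.globals.delta = np.zeros_like(state.globals.delta)
        _, X = toy_data(rng)
        mu = expected_abundance(state, X)
        np.testing.assert_allclose(mu, [[g.y0 for g in state.genes]] * X.shape[0], rtol=1e-12)

    def test_exposure_is_multiplicative(self):
        rng = np.random.default_rng(1)
        state = toy_state(rng)
        _, X = toy_data(rng)
        mu = expected_abundance(state, X)
        state.globals.delta = state.globals.delta + np.log(2.0)
        np.testing.assert_allclose(expected_abundance(state, X), 2 * mu, rtol=1e-12)

    def test_single_cell_composition(self):
        rng = np.random.default_rng(2)
        state = toy_state(rng, G=1, T=1)
        X = np.array([[0.7, -0.2]])
        mu = expected_abundance(state, X)
        expected = np.exp(state.globals.delta[0]) * gla(X[0], state.genes[0])
        assert mu[0, 0] == pytest.approx(expected, rel=1e-12)


class TestHorseshoePrior:
    def test_slab_limits(self):
        lam = np.array([0.5, 2.0, 50.0])
        # huge slab: lam_tilde -> lam (plain horseshoe)
        np.testing.assert_allclose(
            regularized_scales(lam, 1.0, 1e8), lam, rtol=1e-6
        )
        # tau*lam huge with finite slab: scale capped at c
        assert regularized_scales(np.array([1e8]), 1.0, 0.5)[0] == pytest.approx(0.5, rel=1e-6)

    def test_term_by_term_decomposition(self):
        cfg = HorseshoeConfig()
        rng = np.random.default_rng(3)
        beta1 = rng.normal(0, 0.1, size=6)
        lam = np.abs(rng.standard_cauchy(6)) + 0.1
        tau, c, T = 0.3, 0.6, 13
        total = horseshoe_log_prior(beta1, lam, tau, c, cfg, T)
        scales = regularized_scales(lam, tau, c)
        manual = (
            np.sum(stats.norm.logpdf(beta1, 0, scales))
            + np.sum(np.log(2) + stats.t.logpdf(lam, df=1, scale=1.0))
            + np.log(2)
            + stats.t.logpdf(tau, df=1, scale=cfg.tau0(T))
            + stats.invgamma.logpdf(c**2, a=2.0, scale=2.0 * 0.25)
        )
        assert total == pytest.approx(manual, abs=1e-8)

    def test_rejects_non_positive_latents(self):
        with pytest.raises(InvalidArgumentError):
            horseshoe_log_prior(np.zeros(2), np.array([1.0, -1.0]), 0.1, 0.5, HorseshoeConfig(), 13)

    def test_prior_draws_are_sparse_with_heavy_tails(self):
        # ancestral sampling of the stated prior: mass piled near zero, far tails
        rng = np.random.default_rng(7)
        n, T = 10000, 13
        cfg = HorseshoeConfig()
        lam = np.abs(rng.standard_t(cfg.nu_local, n))
        tau = cfg.tau0(T) * np.abs(rng.standard_t(cfg.nu_global, n))
        c2 = cfg.slab_scale**2 * cfg.slab_df / rng.chisquare(cfg.slab_df, n)
        beta1 = rng.standard_normal(n) * regularized_scales(lam, tau, np.sqrt(c2))
        a = np.abs(beta1)
        med, q95, q99 = np.median(a), np.quantile(a, 0.95), np.quantile(a, 0.99)
        assert med < 0.1  # concentration near zero
        assert med < 0.15 * q95  # most mass well inside the tail scale
        assert q99 > 5 * med  # heavy tails


class TestJointLogDensity:
    def test_decomposition_oracle(self):
        # the joint equals the independently summed component densities
        rng = np.random.default_rng(5)
        Y, X = toy_data(rng)
        cfg = HorseshoeConfig()
        for _ in range(50):
            state = toy_state(rng)
            total = joint_log_density(state, Y, X, cfg)
            g = state.globals
            mu = expected_abundance(state, X)
            manual = float(np.sum(nb_log_pmf(Y.T, mu, g.omega)))
            manual += horseshoe_log_prior(
                state.beta1(), g.hs_local_scales, g.hs_global_scale, g.hs_slab, cfg, X.shape[0]
            )
            b_nuis = np.stack([gene.beta[1:] for gene in state.genes])
            manual += float(np.sum(stats.norm.logpdf(b_nuis, 0, g.sigma)))
            manual += float(np.sum(stats.halfnorm.logpdf(g.sigma, 0, 1)))
            y0 = np.array([gene.y0 for gene in state.genes])
            manual += float(
                np.sum(stats.gamma.logpdf(y0, a=g.gamma1 + 1.0, scale=1.0 / g.gamma2))
            )
            manual += float(stats.expon.logpdf(g.gamma1) + stats.expon.logpdf(g.gamma2))
            manual += float(stats.gamma.logpdf(g.omega, a=1.02, scale=0.5))
            eta = np.array([gene.eta for gene in state.genes])
            manual += float(np.sum(stats.norm.logpdf(eta)))
            manual += float(np.sum(stats.norm.logpdf(g.delta)))
            manual += float(
                stats.norm.logpdf(np.sum(g.delta), 0, DELTA_SUM_SD * X.shape[0])
            )
            assert total == pytest.approx(manual, abs=1e-8)

    def test_moving_a_count_off_its_mode_lowers_the_density(self):
        rng = np.random.default_rng(6)
        Y, X = toy_data(rng)
        state = toy_state(rng)
        base = joint_log_density(state, Y, X, HorseshoeConfig())
        Y2 = Y.copy()
        Y2[0, 0] += 5000
        assert joint_log_density(state, Y2, X, HorseshoeConfig()) < base

    def test_finite_on_random_valid_state(self):
        rng = np.random.default_rng(7)
        Y, X = toy_data(rng)
        assert np.isfinite(joint_log_density(toy_state(rng), Y, X, HorseshoeConfig()))

    def test_invariant_under_gene_reordering(self):
        rng = np.random.default_rng(8)
        Y, X = toy_data(rng)
        state = toy_state(rng)
        lp = joint_log_density(state, Y, X, HorseshoeConfig())
        perm = rng.permutation(len(state.genes))
        state2 = ModelState(
            globals=GlobalParams(
                delta=state.globals.delta,
                omega=state.globals.omega,
                sigma=state.globals.sigma,
                gamma1=state.globals.gamma1,
                gamma2=state.globals.gamma2,
                hs_global_scale=state.globals.hs_global_scale,
                hs_local_scales=state.globals.hs_local_scales[perm],
                hs_slab=state.globals.hs_slab,
            ),
            genes=[state.genes[i] for i in perm],
        )
        assert joint_log_density(state2, Y[perm], X, HorseshoeConfig()) == pytest.approx(lp, abs=1e-8)

    def test_exposure_shift_is_penalised(self):
        # adding +1 to every delta (compensating the mean through y0) must
        # lower the density: the soft sum constraint breaks the shift symmetry
        rng = np.random.default_rng(9)
        Y, X = toy_data(rng)
        state = toy_state(rng)
        base = joint_log_density(state, Y, X, HorseshoeConfig())
        shifted = ModelState(
            globals=GlobalParams(
                delta=state.globals.delta + 1.0,
                omega=state.globals.omega,
                sigma=state.globals.sigma,
                gamma1=state.globals.gamma1,
                gamma2=state.globals.gamma2,
                hs_global_scale=state.globals.hs_global_scale,
                hs_local_scales=state.globals.hs_local_scales,
                hs_slab=state.globals.hs_slab,
            ),
            genes=[
                GeneCurveParams(y0=g.y0 / np.e, beta=g.beta, eta=g.eta)
                for g in state.genes
            ],
        )
        assert joint_log_density(shifted, Y, X, HorseshoeConfig()) < base


class TestUnconstrainedModel:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(10)
        Y, X = toy_data(rng, G=6, T=5)
        model = UnconstrainedModel(Y, X)
        theta = model.initial_point(rng) + 0.3 * rng.standard_normal(model.n_dim)
        lp, grad = model.logp_grad(theta)
        assert np.isfinite(lp)
        eps = 1e-5
        for i in range(model.n_dim):
            up, dn = theta.copy(), theta.copy()
            up[i] += eps
            dn[i] -= eps
            fd = (model.logp(up) - model.logp(dn)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-4)

    def test_density_consistent_with_natural_space(self):
        # unconstrained logp = natural joint + log|Jacobian| of the transforms
        rng = np.random.default_rng(11)
        Y, X = toy_data(rng, G=4, T=5)
        model = UnconstrainedModel(Y, X)
        theta = model.initial_point(rng) + 0.2 * rng.standard_normal(model.n_dim)
        state = model.unpack(theta)
        natural = joint_log_density(state, Y, X, model.cfg)
        g = state.globals
        # log-transform Jacobians for every positive parameter sampled on log scale
        jac = (
            np.sum(np.log(g.hs_local_scales))
            + np.sum(np.log([gene.y0 for gene in state.genes]))
            + np.sum(np.log(g.sigma))
            + np.log(g.hs_global_scale)
            + np.log(g.hs_slab**2)
            + np.log(g.omega)
            + np.log(g.gamma1)
            + np.log(g.gamma2)
        )
        # non-centring Jacobians: beta1 = z1 * m, beta_k = z * sigma_k
        m = regularized_scales(g.hs_local_scales, g.hs_global_scale, g.hs_slab)
        jac += np.sum(np.log(m)) + Y.shape[0] * np.sum(np.log(g.sigma))
        lp, _ = model.logp_grad(theta)
        assert lp == pytest.approx(natural + jac, abs=1e-6)

    def test_elementary_logpdfs_match_scipy(self):
        x = np.array([0.3, 1.7])
        np.testing.assert_allclose(_normal_logpdf(x, 2.0), stats.norm.logpdf(x, 0, 2.0))
        np.testing.assert_allclose(
            _half_normal_logpdf(x, 1.0), stats.halfnorm.logpdf(x)
        )
        np.testing.assert_allclose(
            _half_student_t_logpdf(x, 3.0, 0.7),
            np.log(2) + stats.t.logpdf(x, df=3.0, scale=0.7),
        )
        np.testing.assert_allclose(
            _gamma_logpdf(x, 2.5, 1.3), stats.gamma.logpdf(x, a=2.5, scale=1 / 1.3)
        )
        np.testing.assert_allclose(
            _scaled_inv_chi2_logpdf(x, 4.0, 0.25),
            stats.invgamma.logpdf(x, a=2.0, scale=2.0 * 0.25),
        )
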