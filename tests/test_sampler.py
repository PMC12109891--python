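"""Full-conditional draws, ASIS moves and the Gibbs loop."""

import numpy as np
import pytest
from scipy import stats

from pglogit import (
    PanelDataset,
    ParameterState,
    PriorConfig,
    SamplerConfig,
    compute_blocks,
    run_gibbs,
    sample_pg,
)
from pglogit.model import SufficientBlocks
from pglogit.sampler import (
    asis_interweave,
    draw_alpha,
    draw_beta,
    draw_hyper,
    draw_omega,
    from_ancillary,
    to_ancillary,
)

from conftest import make_simple_panel, simple_design


def _blocks(kappa_sums, Z, x_bar, Omega_diag, V_diag):
    kappa = np.array([])  # unused by the draws under test
    return SufficientBlocks(
        kappa, np.asarray(kappa_sums, float), np.atleast_2d(np.asarray(Z, float)),
        np.asarray(x_bar, float), np.asarray(Omega_diag, float), np.asarray(V_diag, float),
    )


class TestDrawOmega:
    def test_length_and_positivity(self, tiny_dataset):
        state = ParameterState(np.zeros(3), np.zeros(1), 0.0, 1.0)
        rng = np.random.default_rng(0)
        omega = draw_omega(tiny_dataset, state, rng)
        assert omega.shape == (tiny_dataset.RT,)
        assert np.all(omega > 0)

    def test_zero_predictor_mean_quarter(self, tiny_dataset):
        state = ParameterState(np.zeros(3), np.zeros(1), 0.0, 1.0)
        rng = np.random.default_rng(1)
        draws = np.concatenate([draw_omega(tiny_dataset, state, rng) for _ in range(3000)])
        se = np.sqrt(1 / 24 / draws.size)
        assert abs(draws.mean() - 0.25) < 3 * se

    def test_distribution_matches_reference_sampler(self):
        data = PanelDataset([1.0], [[1.0]], [0], ["r"])
        state = ParameterState([0.0], [2.0], 0.0, 1.0)  # psi = 2
        rng = np.random.default_rng(2)
        mine = np.concatenate([draw_omega(data, state, rng) for _ in range(30_000)])
        ref = sample_pg(1, 2.0, size=100_000, method="truncated_series", random_state=3)
        assert stats.ks_2samp(mine, ref).pvalue > 0.001


class TestDrawAlpha:
    def test_hand_substitution_moments(self):
        blocks = _blocks([1.0], [[0.0]], [0.0], [1.0, 1.0], [2.0])
        state = ParameterState([0.0], [0.0], 0.0, 1.0)
        priors = PriorConfig.default(1)
        rng = np.random.default_rng(4)
        draws = np.array([draw_alpha(blocks, state, priors, rng)[0] for _ in range(40_000)])
        assert draws.mean() == pytest.approx(1 / 3, abs=3 * np.sqrt(1 / 3 / 40_000))
        assert draws.var() == pytest.approx(1 / 3, rel=0.05)

    def test_vanishing_prior_precision_limit(self):
        blocks = _blocks([1.0], [[1.0]], [0.0], [1.0], [2.0])
        state = ParameterState([0.0], [0.5], 0.0, 1e12)
        priors = PriorConfig.default(1)
        rng = np.random.default_rng(5)
        draws = np.array([draw_alpha(blocks, state, priors, rng)[0] for _ in range(20_000)])
        # mean -> V^{-1}(kappa_sums - Z beta) = (1 - 0.5) / 2
        assert draws.mean() == pytest.approx(0.25, abs=0.02)


class TestDrawBeta:
    def test_unit_fixture_moments(self):
        data = PanelDataset([1.0, 0.0], [[1.0], [1.0]], [0, 0], ["r"])
        blocks = compute_blocks(data, np.ones(2))
        state = ParameterState([0.0], [0.0], 0.0, 1.0)
        priors = PriorConfig(mu_beta=[0.0], A_beta=[[1.0]])
        rng = np.random.default_rng(6)
        draws = np.array([draw_beta(data, blocks, state, priors, rng)[0] for _ in range(40_000)])
        assert draws.mean() == pytest.approx(0.0, abs=3 * np.sqrt(1 / 3 / 40_000))
        assert draws.var() == pytest.approx(1 / 3, rel=0.05)

    def test_dominant_prior_collapses_to_prior_mean(self):
        data = PanelDataset([1.0, 0.0], [[1.0], [1.0]], [0, 0], ["r"])
        blocks = compute_blocks(data, np.ones(2))
        state = ParameterState([0.0], [0.0], 0.0, 1.0)
        priors = PriorConfig(mu_beta=[0.7], A_beta=[[1e10]])
        rng = np.random.default_rng(7)
        draw = draw_beta(data, blocks, state, priors, rng)
        assert draw[0] == pytest.approx(0.7, abs=1e-3)


class TestDrawHyper:
    def test_flat_hyperprior_recovers_sample_mean(self):
        state = ParameterState(np.full(50, 1.3), np.zeros(1), 0.0, 1.0)
        priors = PriorConfig(mu_beta=[0.0], A_beta=[[1.0]], sigma0_sq=1e12)
        rng = np.random.default_rng(8)
        mus = np.array([draw_hyper(state, priors, rng)[0] for _ in range(20_000)])
        assert mus.mean() == pytest.approx(1.3, abs=3 * np.sqrt(1.0 / 50 / 20_000) + 1e-3)

    def test_inverse_gamma_scale_example(self):
        """R = 2, alpha = (1, -1), mu = 0, nu0 = lambda0 = 2 gives
        sigma^2 | . ~ IG(2, 2), whose mean is 2."""
        priors = PriorConfig(mu_beta=[0.0], A_beta=[[1.0]], sigma0_sq=1e-12, nu0=2.0, lambda0=2.0)
        state = ParameterState(np.array([1.0, -1.0]), np.zeros(1), 0.0, 1.0)
        rng = np.random.default_rng(9)
        s2 = np.array([draw_hyper(state, priors, rng)[1] for _ in range(40_000)])
        # IG(2,2): mean 2, variance infinite -> compare trimmed/robust quantity
        assert np.median(s2) == pytest.approx(2 / stats.gamma(2).median(), rel=0.03)
        assert s2.mean() == pytest.approx(2.0, rel=0.15)

    def test_posterior_shape_grows_by_half_r(self):
        rng = np.random.default_rng(10)
        for r in (1, 7, 40):
            state = ParameterState(rng.normal(size=r), np.zeros(1), 0.0, 1.0)
            priors = PriorConfig.default(1)
            # shape used internally is (r + nu0)/2; verify via the draw's law
            s2 = np.array([draw_hyper(state, priors, rng)[1] for _ in range(5000)])
            assert np.all(s2 > 0)


class TestASIS:
    def test_ancillary_round_trip_is_identity(self):
        rng = np.random.default_rng(11)
        state = ParameterState(rng.normal(size=20), rng.normal(size=3), 0.4, 2.3)
        tilde = to_ancillary(state)
        back = from_ancillary(tilde, state.mu_alpha, state.sigma_alpha_sq)
        np.testing.assert_allclose(back, state.alpha, rtol=0, atol=1e-14)

    def test_interweave_requires_omega(self, tiny_dataset):
        state = ParameterState(np.zeros(3), np.zeros(1), 0.0, 1.0)
        with pytest.raises(ValueError, match="omega"):
            asis_interweave(tiny_dataset, state, PriorConfig.default(1), np.random.default_rng(0))

    def test_interweave_preserves_support(self, tiny_dataset):
        rng = np.random.default_rng(12)
        state = ParameterState(rng.normal(size=3), rng.normal(size=1), 0.0, 1.0)
        state.omega = draw_omega(tiny_dataset, state, rng)
        for _ in range(200):
            state = asis_interweave(tiny_dataset, state, PriorConfig.default(1), rng)
            assert state.sigma_alpha_sq > 0
            assert np.isfinite(state.alpha).all()


def _geweke_chain(n_sweeps, seed, use_asis):
    """Successive-conditional simulator: alternate theta | y and y | theta.

    If every full conditional is correct, the theta marginals equal the
    prior, whatever the data size.
    """
    rng = np.random.default_rng(seed)
    R, T, K = 12, 4, 2
    X = rng.normal(size=(R * T, K))
    ridx = np.repeat(np.arange(R), T)
    priors = PriorConfig(
        mu_beta=np.zeros(K), A_beta=np.eye(K), mu0=0.0, sigma0_sq=1.0, nu0=10.0, lambda0=10.0
    )
    s2 = priors.lambda0 / 2 / rng.gamma(priors.nu0 / 2)
    mu = rng.normal(priors.mu0, np.sqrt(priors.sigma0_sq))
    state = ParameterState(rng.normal(mu, np.sqrt(s2), R), rng.normal(size=K), mu, s2)
    data = PanelDataset(np.zeros(R * T), X, ridx, np.arange(R))
    out = np.empty((n_sweeps, 3))
    for i in range(n_sweeps):
        psi = state.alpha[ridx] + X @ state.beta
        data.y = (rng.random(R * T) < 1 / (1 + np.exp(-psi))).astype(float)
        state.omega = draw_omega(data, state, rng)
        blocks = compute_blocks(data, state.omega)
        state.alpha = draw_alpha(blocks, state, priors, rng)
        state.beta = draw_beta(data, blocks, state, priors, rng)
        state.mu_alpha, state.sigma_alpha_sq = draw_hyper(state, priors, rng)
        if use_asis:
            state = asis_interweave(data, state, priors, rng)
        out[i] = state.mu_alpha, state.sigma_alpha_sq, state.beta[0]
    return out, priors


@pytest.mark.parametrize("use_asis", [False, True])
def test_geweke_joint_consistency(use_asis):
    """Alternating parameter and data redraws must reproduce the prior
    marginals of mu_alpha, sigma_alpha^2 and beta."""
    import arviz as az

    chain, priors = _geweke_chain(8000, seed=20 + use_asis, use_asis=use_asis)
    chain = chain[500:]
    names = ["mu_alpha", "sigma_alpha_sq", "beta0"]
    # prior moments: mu ~ N(0,1); s2 ~ IG(5,5): mean 1.25, sd 1.25/sqrt(3); b ~ N(0,1)
    prior_mean = {"mu_alpha": 0.0, "sigma_alpha_sq": 1.25, "beta0": 0.0}
    prior_sd = {"mu_alpha": 1.0, "sigma_alpha_sq": 1.25 / np.sqrt(3), "beta0": 1.0}
    for j, name in enumerate(names):
        x = chain[:, j]
        ess = float(az.ess(x[None, :]))
        se = prior_sd[name] / np.sqrt(max(ess, 10.0))
        assert abs(x.mean() - prior_mean[name]) < 3 * se, (name, x.mean(), ess)


class TestRunGibbs:
    def test_determinism(self):
        table, _ = make_simple_panel(n_respondents=25, k=2, seed=30)
        data = simple_design(table, 2)
        cfg = SamplerConfig(n_iter=60, n_burn=20, n_chains=2, seed=77)
        a = run_gibbs(data, config=cfg)
        b = run_gibbs(data, config=cfg)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.log_lik, b.log_lik)

    def test_constant_outcome_respondent_rejected(self):
        data = PanelDataset([1, 1, 1, 1, 0, 1], [[0.0]] * 6, [0, 0, 0, 1, 1, 1], ["a", "b"])
        with pytest.raises(ValueError, match="identical"):
            run_gibbs(data, config=SamplerConfig(n_iter=10, n_burn=0, n_chains=1))

    def test_store_shapes_and_thinning(self):
        table, _ = make_simple_panel(n_respondents=20, k=2, seed=31)
        data = simple_design(table, 2)
        cfg = SamplerConfig(n_iter=101, n_burn=21, n_chains=2, thin=4, seed=1)
        d = run_gibbs(data, config=cfg)
        assert d.alpha.shape == (2, 20, data.R)
        assert d.beta.shape == (2, 20, 2)
        assert d.log_lik.shape == (2, 20, data.RT)
        assert np.all(d.sigma_alpha_sq > 0)

    def test_posterior_mean_matches_quadrature_oracle(self, tiny_dataset):
        """Exactness check: the PG-Gibbs posterior mean of beta (and of
        sigma_alpha^2) on a tiny fixture agrees with deterministic grid
        quadrature of the unaugmented posterior."""
        from quadrature_oracle import grid_posterior_means

        priors = PriorConfig(mu_beta=[0.0], A_beta=[[0.25]], mu0=0.0, sigma0_sq=4.0, nu0=4.0, lambda0=4.0)
        e_beta, e_mu, e_s2 = grid_posterior_means(tiny_dataset, priors)
        d = run_gibbs(tiny_dataset, priors, SamplerConfig(n_iter=12000, n_burn=2000, n_chains=2, seed=9, store_log_lik=False))
        assert d.beta.mean() == pytest.approx(e_beta, abs=0.02)
        assert d.sigma_alpha_sq.mean() == pytest.approx(e_s2, rel=0.05)
        assert d.mu_alpha.mean() == pytest.approx(e_mu, abs=0.05)

    def test_asis_on_off_target_same_posterior(self):
        """Interweaved and plain chains agree on every scalar summary
        within combined Monte Carlo error."""
        import arviz as az

        table, _ = make_simple_panel(n_respondents=40, k=3, seed=33)
        data = simple_design(table, 3)
        d_on = run_gibbs(data, config=SamplerConfig(n_iter=4000, n_burn=1000, n_chains=2, seed=50, use_asis=True, store_log_lik=False))
        d_off = run_gibbs(data, config=SamplerConfig(n_iter=4000, n_burn=1000, n_chains=2, seed=51, use_asis=False, store_log_lik=False))
        worst = 0.0
        for (name, a), (_, b) in zip(d_on.iter_parameters(), d_off.iter_parameters()):
            ess_a = max(float(az.ess(a)), 20.0)
            ess_b = max(float(az.ess(b)), 20.0)
            se = np.sqrt(a.var(ddof=1) / ess_a + b.var(ddof=1) / ess_b)
            z = abs(a.mean() - b.mean()) / max(se, 1e-12)
            worst = max(worst, z)
        assert worst < 4.0  # joint over ~45 comparisons
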