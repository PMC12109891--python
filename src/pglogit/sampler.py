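"""Pólya–Gamma Gibbs sampler with ASIS interweaving.

One sweep updates, in order,

    omega_rt | .  ~ PG(1, psi_rt)                     (augmentation refresh)
    alpha    | .  ~ N((V + sigma_a^{-2} I)^{-1} (Ksum - Z beta
                      + mu_a sigma_a^{-2} 1), (V + sigma_a^{-2} I)^{-1})
    beta     | .  ~ N((X' Omega X + A_b)^{-1} (xbar - Z' alpha
                      + A_b mu_b), (X' Omega X + A_b)^{-1})
    mu_a     | .  ~ N((sigma_a^{-2} sum alpha + sigma0^{-2} mu0) / P, 1 / P),
                      P = sigma_a^{-2} R + sigma0^{-2}
    sigma_a^2| .  ~ InvGamma((R + nu0) / 2, (sum (alpha_r - mu_a)^2
                      + lambda0) / 2)

optionally followed by an ancillarity–sufficiency interweaving (ASIS)
move: the intercepts are re-expressed in the non-centred (ancillary)
parameterization alpha~_r = (alpha_r - mu_a) / sigma_a, the location
mu_a is redrawn exactly (its ancillary conditional given omega is
Gaussian) and sigma_a^2 via Metropolis steps on log sigma_a^2 against its
exact ancillary conditional, and the intercepts are mapped back.  The
interweave leaves the joint posterior invariant while breaking the strong
coupling between the intercepts and their hyperparameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg as sla

from .model import (
    PanelDataset,
    ParameterState,
    PriorConfig,
    SufficientBlocks,
    compute_blocks,
    linear_predictor,
    pointwise_log_likelihood,
)
from .polya_gamma import sample_pg

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "draw_omega",
    "draw_alpha",
    "draw_beta",
    "draw_hyper",
    "asis_interweave",
    "run_gibbs",
]


@dataclass
class SamplerConfig:
    n_iter: int = 6000
    n_burn: int = 1000
    n_chains: int = 4
    thin: int = 1
    use_asis: bool = True
    pg_method: str = "exact"
    series_terms: int = 200
    asis_mh_steps: int = 2
    asis_step_size: float = 0.25
    store_log_lik: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (self.n_iter > self.n_burn >= 0):
            raise ValueError("need n_iter > n_burn >= 0")
        if self.n_chains < 1 or self.thin < 1 or self.series_terms < 1:
            raise ValueError("n_chains, thin and series_terms must be >= 1")
        if self.pg_method not in ("exact", "truncated_series"):
            raise ValueError(f"unknown pg_method {self.pg_method!r}")

    @property
    def n_store(self) -> int:
        return (self.n_iter - self.n_burn + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """Multi-chain draw store, indexed (chain, stored iteration, parameter).

    The pointwise log-likelihood matrix is retained per stored draw so
    information criteria can be computed without re-touching the data.
    """

    alpha: np.ndarray  # (C, S, R)
    beta: np.ndarray  # (C, S, K)
    mu_alpha: np.ndarray  # (C, S)
    sigma_alpha_sq: np.ndarray  # (C, S)
    log_lik: np.ndarray | None  # (C, S, RT) or None
    respondent_ids: np.ndarray
    column_names: list
    config: SamplerConfig | None = None

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    @property
    def parameter_names(self) -> list:
        return (
            [f"alpha[{rid}]" for rid in self.respondent_ids]
            + [f"beta[{c}]" for c in self.column_names]
            + ["mu_alpha", "sigma_alpha_sq"]
        )

    def chains(self, name: str) -> np.ndarray:
        """Draws for one named parameter, shape (chains, stored draws)."""
        if name == "mu_alpha":
            return self.mu_alpha
        if name == "sigma_alpha_sq":
            return self.sigma_alpha_sq
        if name.startswith("alpha["):
            rid = name[6:-1]
            (pos,) = np.flatnonzero(self.respondent_ids.astype(str) == rid)
            return self.alpha[:, :, pos]
        if name.startswith("beta["):
            col = name[5:-1]
            pos = self.column_names.index(col)
            return self.beta[:, :, pos]
        raise KeyError(name)

    def stacked(self, name: str) -> np.ndarray:
        """All chains pooled, shape (total draws,)."""
        return self.chains(name).reshape(-1)

    def iter_parameters(self):
        """Yield (name, (chains, draws) array) over every sampled scalar."""
        for j, rid in enumerate(self.respondent_ids):
            yield f"alpha[{rid}]", self.alpha[:, :, j]
        for j, col in enumerate(self.column_names):
            yield f"beta[{col}]", self.beta[:, :, j]
        yield "mu_alpha", self.mu_alpha
        yield "sigma_alpha_sq", self.sigma_alpha_sq

    def pooled_log_lik(self) -> np.ndarray:
        """(total draws, RT) pointwise log-likelihood matrix."""
        if self.log_lik is None:
            raise ValueError("log-likelihood matrix was not stored")
        c, s, rt = self.log_lik.shape
        return self.log_lik.reshape(c * s, rt)

    def to_frame(self):
        """Long-format frame (chain, iteration, parameter, value)."""
        import pandas as pd

        records = []
        for name, arr in self.iter_parameters():
            c, s = arr.shape
            records.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), s),
                        "iteration": np.tile(np.arange(s), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(records, ignore_index=True)


def draw_omega(data: PanelDataset, state: ParameterState, rng: np.random.Generator,
               method: str = "exact", series_terms: int = 200) -> np.ndarray:
    """Refresh the augmentation: omega_rt ~ PG(1, psi_rt)."""
    psi = linear_predictor(data, state)
    return sample_pg(1, psi, method=method, series_terms=series_terms, random_state=rng)


def draw_alpha(blocks: SufficientBlocks, state: ParameterState, priors: PriorConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Intercept update; V diagonal makes the coordinates independent."""
    if state.sigma_alpha_sq <= 0:
        raise ValueError("sigma_alpha_sq outside support")
    prec = blocks.V_diag + 1.0 / state.sigma_alpha_sq
    mean = (blocks.kappa_sums - blocks.Z @ state.beta + state.mu_alpha / state.sigma_alpha_sq) / prec
    return mean + rng.standard_normal(mean.shape[0]) / np.sqrt(prec)


def draw_beta(data: PanelDataset, blocks: SufficientBlocks, state: ParameterState,
              priors: PriorConfig, rng: np.random.Generator) -> np.ndarray:
    """Slope update from its Gaussian full conditional via a Cholesky
    factorization of the precision X' Omega X + A_beta."""
    P = data.X.T @ (blocks.Omega_diag[:, None] * data.X) + priors.A_beta
    b = blocks.x_bar - blocks.Z.T @ state.alpha[: data.R] + priors.A_beta @ priors.mu_beta
    try:
        chol = sla.cho_factor(P, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            "precision X'OmegaX + A_beta is not positive definite; "
            "consider a stronger slope prior (larger A_beta)"
        ) from exc
    mean = sla.cho_solve(chol, b)
    z = rng.standard_normal(mean.shape[0])
    return mean + sla.solve_triangular(chol[0], z, lower=True, trans="T")


def draw_hyper(state: ParameterState, priors: PriorConfig, rng: np.random.Generator):
    """(mu_alpha, sigma_alpha_sq) from their conjugate conditionals."""
    alpha = state.alpha
    r = alpha.shape[0]
    if r < 1:
        raise ValueError("need at least one respondent")
    prec = r / state.sigma_alpha_sq + 1.0 / priors.sigma0_sq
    mean = (alpha.sum() / state.sigma_alpha_sq + priors.mu0 / priors.sigma0_sq) / prec
    mu_alpha = mean + rng.standard_normal() / np.sqrt(prec)
    shape = 0.5 * (r + priors.nu0)
    scale = 0.5 * (np.sum((alpha - mu_alpha) ** 2) + priors.lambda0)
    sigma_alpha_sq = scale / rng.gamma(shape)
    return float(mu_alpha), float(sigma_alpha_sq)


def to_ancillary(state: ParameterState) -> np.ndarray:
    """alpha~_r = (alpha_r - mu_alpha) / sigma_alpha."""
    return (state.alpha - state.mu_alpha) / np.sqrt(state.sigma_alpha_sq)


def from_ancillary(alpha_tilde: np.ndarray, mu_alpha: float, sigma_alpha_sq: float) -> np.ndarray:
    return mu_alpha + np.sqrt(sigma_alpha_sq) * alpha_tilde


def asis_interweave(data: PanelDataset, state: ParameterState, priors: PriorConfig,
                    rng: np.random.Generator, *, mh_steps: int = 2, step_size: float = 0.25) -> ParameterState:
    """Redraw (mu_alpha, sigma_alpha^2) in the ancillary parameterization.

    Conditional on the current omega, psi_rt = mu_a + sigma_a alpha~_r +
    x_rt' beta enters a Gaussian pseudo-likelihood, so mu_a is conjugate.
    sigma_a^2 is updated by random-walk Metropolis on log sigma_a^2
    against its exact ancillary conditional (InvGamma prior + Jacobian +
    pseudo-likelihood terms); a rejected proposal leaves the state
    unchanged, which is still valid MCMC.
    """
    if state.omega is None:
        raise ValueError("state.omega must be set before interweaving")
    omega = state.omega
    idx = data.respondent_index
    r = data.R
    alpha_tilde = to_ancillary(state)
    c_row = data.X @ state.beta  # non-intercept part of psi
    kappa = data.y - 0.5
    v_r = np.bincount(idx, weights=omega, minlength=r)
    k_r = np.bincount(idx, weights=kappa, minlength=r)
    w_r = np.bincount(idx, weights=omega * c_row, minlength=r)

    # --- exact Gaussian redraw of mu_alpha ---
    s = np.sqrt(state.sigma_alpha_sq)
    prec = omega.sum() + 1.0 / priors.sigma0_sq
    num = kappa.sum() - float(v_r @ (s * alpha_tilde)) - w_r.sum() + priors.mu0 / priors.sigma0_sq
    mu_new = num / prec + rng.standard_normal() / np.sqrt(prec)

    # --- Metropolis on u = log sigma_alpha^2 ---
    a_lin = float(alpha_tilde @ (k_r - w_r - mu_new * v_r))
    b_quad = float((alpha_tilde**2) @ v_r)

    def log_target(u: float) -> float:
        sd = np.exp(0.5 * u)
        return -0.5 * priors.nu0 * u - 0.5 * priors.lambda0 * np.exp(-u) + sd * a_lin - 0.5 * sd * sd * b_quad

    u = float(np.log(state.sigma_alpha_sq))
    lt = log_target(u)
    accepted = False
    for _ in range(mh_steps):
        u_prop = u + step_size * rng.standard_normal()
        lt_prop = log_target(u_prop)
        if np.log(rng.random()) < lt_prop - lt:
            u, lt = u_prop, lt_prop
            accepted = True
    if not accepted:
        logger.debug("ASIS scale move: no acceptance in %d proposals", mh_steps)
    sigma_new = float(np.exp(u))
    alpha_new = from_ancillary(alpha_tilde, float(mu_new), sigma_new)
    return ParameterState(alpha_new, state.beta, float(mu_new), sigma_new, omega)


def run_gibbs(data: PanelDataset, priors: PriorConfig | None = None,
              config: SamplerConfig | None = None, progress: bool = False) -> PosteriorDraws:
    """Run the full Gibbs sampler and return the multi-chain draw store.

    Chains are seeded from independent substreams of ``config.seed``, so
    identical inputs reproduce identical draws.
    """
    config = config or SamplerConfig()
    priors = priors or PriorConfig.default(data.K)
    if priors.mu_beta.shape[0] != data.K:
        raise ValueError("prior dimension does not match design")
    bad = data.constant_outcome_respondents()
    if len(bad):
        raise ValueError(
            "estimation is not possible if all responses from a respondent are "
            f"identical; constant-outcome respondents present: {list(map(str, bad[:5]))}"
            f"{'...' if len(bad) > 5 else ''}"
        )
    n_store = config.n_store
    C, R, K, RT = config.n_chains, data.R, data.K, data.RT
    draws = PosteriorDraws(
        alpha=np.empty((C, n_store, R)),
        beta=np.empty((C, n_store, K)),
        mu_alpha=np.empty((C, n_store)),
        sigma_alpha_sq=np.empty((C, n_store)),
        log_lik=np.empty((C, n_store, RT)) if config.store_log_lik else None,
        respondent_ids=data.respondent_ids,
        column_names=list(data.column_names),
        config=config,
    )
    chain_seeds = np.random.SeedSequence(config.seed).spawn(C)
    for c in range(C):
        rng = np.random.default_rng(chain_seeds[c])
        state = ParameterState.initial(R, K)
        stored = 0
        for it in range(config.n_iter):
            state.omega = draw_omega(data, state, rng, config.pg_method, config.series_terms)
            blocks = compute_blocks(data, state.omega)
            state.alpha = draw_alpha(blocks, state, priors, rng)
            state.beta = draw_beta(data, blocks, state, priors, rng)
            state.mu_alpha, state.sigma_alpha_sq = draw_hyper(state, priors, rng)
            if config.use_asis:
                state = asis_interweave(
                    data, state, priors, rng,
                    mh_steps=config.asis_mh_steps, step_size=config.asis_step_size,
                )
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
                draws.alpha[c, stored] = state.alpha
                draws.beta[c, stored] = state.beta
                draws.mu_alpha[c, stored] = state.mu_alpha
                draws.sigma_alpha_sq[c, stored] = state.sigma_alpha_sq
                if draws.log_lik is not None:
                    draws.log_lik[c, stored] = pointwise_log_likelihood(data, state)
                stored += 1
            if progress and (it + 1) % 1000 == 0:
                logger.info("chain %d: %d / %d iterations", c, it + 1, config.n_iter)
    return draws
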