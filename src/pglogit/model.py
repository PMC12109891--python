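"""Probability model for the random-intercept panel logit.

Each respondent r contributes T_r binary responses

    y_rt ~ Bernoulli(pi_rt),   pi_rt = logistic(psi_rt),
    psi_rt = alpha_r + x_rt' beta,

with respondent intercepts alpha_r ~ N(mu_alpha, sigma_alpha^2) absorbing
unobserved heterogeneity (there is no global intercept column).  The
hierarchy is closed with conjugate priors

    beta ~ N(mu_beta, A_beta^{-1}),
    mu_alpha ~ N(mu0, sigma0^2),
    sigma_alpha^2 ~ InvGamma(nu0 / 2, lambda0 / 2).

This module holds the data container, the prior and state records, the
likelihood pieces, and the sufficient-statistic blocks consumed by the
Pólya–Gamma Gibbs sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PanelDataset",
    "PriorConfig",
    "ParameterState",
    "SufficientBlocks",
    "linear_predictor",
    "response_probability",
    "log_likelihood",
    "log_posterior_unnormalized",
    "compute_blocks",
    "parameter_count",
]


@dataclass
class PanelDataset:
    """Stacked design for an unbalanced binary panel.

    Rows are ordered respondents-outer, waves-inner; each respondent's
    block is contiguous.  ``respondent_index`` maps row -> 0..R-1.
    """

    y: np.ndarray
    X: np.ndarray
    respondent_index: np.ndarray
    respondent_ids: np.ndarray
    column_names: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.respondent_index = np.asarray(self.respondent_index, dtype=np.intp).ravel()
        self.respondent_ids = np.asarray(self.respondent_ids)
        if not self.column_names:
            self.column_names = [f"x{j + 1}" for j in range(self.X.shape[1])]
        self.validate()

    def validate(self) -> None:
        rt, k = self.X.shape
        if self.y.shape[0] != rt or self.respondent_index.shape[0] != rt:
            raise ValueError("y, X and respondent_index must have matching row counts")
        if k < 1:
            raise ValueError("design must have at least one column")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1 with no missing values")
        idx = self.respondent_index
        if idx.min(initial=0) < 0 or (rt and idx.max() >= len(self.respondent_ids)):
            raise ValueError("respondent_index out of range")
        # blocks must be contiguous and in respondent order (0,0,...,1,1,...)
        if np.any(np.diff(idx) < 0) or len(np.unique(idx)) != len(self.respondent_ids):
            raise ValueError("respondent blocks must be contiguous, ordered, and cover every id")
        if len(self.column_names) != k:
            raise ValueError("column_names length must equal K")

    @property
    def R(self) -> int:
        return len(self.respondent_ids)

    @property
    def K(self) -> int:
        return self.X.shape[1]

    @property
    def RT(self) -> int:
        return self.X.shape[0]

    @property
    def T(self) -> np.ndarray:
        """Per-respondent wave counts T_r (sum equals RT)."""
        return np.bincount(self.respondent_index, minlength=self.R)

    @property
    def block_starts(self) -> np.ndarray:
        return np.r_[0, np.cumsum(self.T)[:-1]]

    def constant_outcome_respondents(self) -> np.ndarray:
        """ids whose response sequence is all ones or all zeros."""
        sums = np.bincount(self.respondent_index, weights=self.y, minlength=self.R)
        t = self.T
        return self.respondent_ids[(sums == 0) | (sums == t)]

    # -- serialization ------------------------------------------------------

    def to_csv(self, design_path, index_path) -> None:
        frame = pd.DataFrame(self.X, columns=self.column_names)
        frame.insert(0, "y", self.y.astype(int))
        frame.insert(0, "respondent_id", self.respondent_ids[self.respondent_index])
        frame.to_csv(design_path, index=False)
        pd.DataFrame({"respondent_id": self.respondent_ids, "T": self.T}).to_csv(index_path, index=False)

    @classmethod
    def from_csv(cls, design_path, index_path) -> "PanelDataset":
        frame = pd.read_csv(design_path)
        index = pd.read_csv(index_path)
        ids = index["respondent_id"].to_numpy()
        order = {rid: i for i, rid in enumerate(ids)}
        ridx = frame["respondent_id"].map(order).to_numpy()
        cols = [c for c in frame.columns if c not in ("respondent_id", "y")]
        return cls(frame["y"].to_numpy(), frame[cols].to_numpy(), ridx, ids, cols)

    @classmethod
    def from_arrays(cls, y, X, groups, column_names=None) -> "PanelDataset":
        """Build from row-wise arrays, sorting rows into contiguous groups.

        Group blocks are ordered by first appearance; within a block the
        original row order is kept.
        """
        groups = np.asarray(groups)
        ids, first = np.unique(groups, return_index=True)
        ids = ids[np.argsort(first)]
        order = {g: i for i, g in enumerate(ids)}
        ridx = np.array([order[g] for g in groups], dtype=np.intp)
        perm = np.argsort(ridx, kind="stable")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return cls(np.asarray(y)[perm], X[perm], ridx[perm], ids, list(column_names or []))


@dataclass
class PriorConfig:
    """Hyperparameters of the conjugate prior hierarchy.

    ``mu0``/``sigma0_sq`` are the mean and variance of the Gaussian prior
    on mu_alpha; ``nu0``/``lambda0`` parameterize the InvGamma(nu0/2,
    lambda0/2) prior on sigma_alpha^2.  The published settings quote
    (phi_alpha, tau_alpha^2, s_alpha, s_eps); those aliases map to
    mu0 = phi_alpha, sigma0_sq = tau_alpha^2, nu0 = 2 s_alpha,
    lambda0 = 2 s_eps.
    """

    mu_beta: np.ndarray
    A_beta: np.ndarray
    mu0: float = 0.0
    sigma0_sq: float = 100.0
    nu0: float = 2.0
    lambda0: float = 2.0

    def __post_init__(self):
        self.mu_beta = np.asarray(self.mu_beta, dtype=float).ravel()
        self.A_beta = np.atleast_2d(np.asarray(self.A_beta, dtype=float))
        k = self.mu_beta.shape[0]
        if self.A_beta.shape != (k, k):
            raise ValueError("A_beta must be K x K matching mu_beta")
        if not np.allclose(self.A_beta, self.A_beta.T):
            raise ValueError("A_beta must be symmetric")
        if np.any(np.linalg.eigvalsh(self.A_beta) <= 0):
            raise ValueError("A_beta must be positive definite")
        if self.sigma0_sq <= 0 or self.nu0 <= 0 or self.lambda0 <= 0:
            raise ValueError("sigma0_sq, nu0, lambda0 must be positive")

    @classmethod
    def default(cls, k: int) -> "PriorConfig":
        """The study's settings: mu_beta = 0, Sigma_beta = 100 I,
        phi_alpha = 0, tau_alpha^2 = 100, s_alpha = s_eps = 1."""
        return cls.from_reported(k)

    @classmethod
    def from_reported(
        cls, k: int, *, beta_var: float = 100.0, phi_alpha: float = 0.0,
        tau_alpha_sq: float = 100.0, s_alpha: float = 1.0, s_eps: float = 1.0,
    ) -> "PriorConfig":
        return cls(
            mu_beta=np.zeros(k),
            A_beta=np.eye(k) / beta_var,
            mu0=phi_alpha,
            sigma0_sq=tau_alpha_sq,
            nu0=2.0 * s_alpha,
            lambda0=2.0 * s_eps,
        )

    @property
    def Sigma_beta(self) -> np.ndarray:
        return np.linalg.inv(self.A_beta)


@dataclass
class ParameterState:
    """One MCMC state (alpha, beta, mu_alpha, sigma_alpha_sq, omega)."""

    alpha: np.ndarray
    beta: np.ndarray
    mu_alpha: float
    sigma_alpha_sq: float
    omega: np.ndarray | None = None

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.sigma_alpha_sq <= 0:
            raise ValueError("sigma_alpha_sq must be positive")
        if self.omega is not None:
            self.omega = np.asarray(self.omega, dtype=float).ravel()
            if np.any(self.omega <= 0):
                raise ValueError("omega must be strictly positive")

    def copy(self) -> "ParameterState":
        return ParameterState(
            self.alpha.copy(), self.beta.copy(), self.mu_alpha, self.sigma_alpha_sq,
            None if self.omega is None else self.omega.copy(),
        )

    @classmethod
    def initial(cls, R: int, K: int) -> "ParameterState":
        return cls(np.zeros(R), np.zeros(K), 0.0, 1.0, None)


@dataclass
class SufficientBlocks:
    """Per-sweep sufficient statistics of the augmented Gaussian likelihood.

    ``kappa`` holds y - 1/2 per row; ``kappa_sums`` its per-respondent
    sums; ``Z`` the omega-weighted per-respondent covariate sums; ``x_bar``
    the kappa-weighted covariate total; ``V_diag`` the per-respondent
    omega totals (diagonal of V).
    """

    kappa: np.ndarray
    kappa_sums: np.ndarray
    Z: np.ndarray
    x_bar: np.ndarray
    Omega_diag: np.ndarray
    V_diag: np.ndarray


def linear_predictor(data: PanelDataset, state: ParameterState) -> np.ndarray:
    """psi_rt = alpha_r + x_rt' beta for every retained row."""
    if state.alpha.shape[0] != data.R or state.beta.shape[0] != data.K:
        raise ValueError("state dimensions do not match dataset")
    return state.alpha[data.respondent_index] + data.X @ state.beta


def response_probability(psi):
    """logistic(psi), overflow-safe for large |psi|."""
    psi_arr = np.asarray(psi, dtype=float)
    if not np.all(np.isfinite(psi_arr)):
        raise ValueError("psi must be finite")
    out = np.empty_like(psi_arr)
    pos = psi_arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-psi_arr[pos]))
    e = np.exp(psi_arr[~pos])
    out[~pos] = e / (1.0 + e)
    return out if np.ndim(psi) else float(out)


def _log1p_exp(psi: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, psi)


def log_likelihood(data: PanelDataset, state: ParameterState) -> float:
    """Bernoulli-logit log likelihood sum_rt [y psi - log(1 + e^psi)]."""
    psi = linear_predictor(data, state)
    return float(np.sum(data.y * psi - _log1p_exp(psi)))


def pointwise_log_likelihood(data: PanelDataset, state: ParameterState) -> np.ndarray:
    """Per-observation log likelihood (the WAIC ingredient)."""
    psi = linear_predictor(data, state)
    return data.y * psi - _log1p_exp(psi)


def log_posterior_unnormalized(data: PanelDataset, state: ParameterState, priors: PriorConfig) -> float:
    """Log of likelihood x priors, up to the normalizing constant.

    Used by test oracles and diagnostics only; the Gibbs sweep never
    evaluates it.
    """
    if state.sigma_alpha_sq <= 0:
        raise ValueError("sigma_alpha_sq outside support")
    ll = log_likelihood(data, state)
    sd_a = np.sqrt(state.sigma_alpha_sq)
    lp = float(np.sum(stats.norm.logpdf(state.alpha, state.mu_alpha, sd_a)))
    resid = state.beta - priors.mu_beta
    sign, logdet = np.linalg.slogdet(priors.A_beta)
    lp += 0.5 * logdet - 0.5 * float(resid @ priors.A_beta @ resid) - 0.5 * len(resid) * np.log(2 * np.pi)
    lp += float(stats.norm.logpdf(state.mu_alpha, priors.mu0, np.sqrt(priors.sigma0_sq)))
    lp += float(stats.invgamma.logpdf(state.sigma_alpha_sq, priors.nu0 / 2.0, scale=priors.lambda0 / 2.0))
    return ll + lp


def compute_blocks(data: PanelDataset, omega: np.ndarray, y: np.ndarray | None = None) -> SufficientBlocks:
    """Recompute all sufficient blocks from scratch for the given omega."""
    omega = np.asarray(omega, dtype=float).ravel()
    if omega.shape[0] != data.RT:
        raise ValueError("omega must have length RT")
    if np.any(omega <= 0):
        raise ValueError("omega must be strictly positive")
    y = data.y if y is None else np.asarray(y, dtype=float).ravel()
    kappa = y - 0.5
    idx = data.respondent_index
    kappa_sums = np.bincount(idx, weights=kappa, minlength=data.R)
    V_diag = np.bincount(idx, weights=omega, minlength=data.R)
    # respondent blocks are contiguous (class invariant), so reduceat applies
    Z = np.add.reduceat(omega[:, None] * data.X, data.block_starts, axis=0)
    x_bar = kappa @ data.X
    return SufficientBlocks(kappa, kappa_sums, Z, x_bar, omega, V_diag)


def parameter_count(spec, R: int) -> int:
    """Number of sampled model parameters: R intercepts + K slopes +
    (mu_alpha, sigma_alpha^2).  Pólya–Gamma latents are augmentation
    variables and are not counted."""
    if hasattr(spec, "covariate_names"):
        k = len(spec.covariate_names)
    else:
        k = int(spec)
    return int(R) + k + 2
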