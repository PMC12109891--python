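"""scikit-learn style front end for the Bayesian panel logit.

``BayesianPanelLogit`` wraps the Pólya–Gamma Gibbs sampler behind the
familiar ``fit`` / ``predict_proba`` surface so it composes with sklearn
pipelines and model selection.  ``fit`` takes the stacked long-format
design together with a ``groups`` vector of respondent identifiers; the
fitted attributes expose posterior means and the full draw store.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .model import PanelDataset, PriorConfig
from .sampler import PosteriorDraws, SamplerConfig, run_gibbs
from .summary import FitSummary, summarize

__all__ = ["BayesianPanelLogit"]


class BayesianPanelLogit(ClassifierMixin, BaseEstimator):
    """Random-intercept logit fitted by Pólya–Gamma Gibbs sampling.

    Parameters
    ----------
    n_iter, n_burn, n_chains, thin : MCMC schedule.
    use_asis : apply the ancillarity–sufficiency interweaving move after
        each sweep (recommended; greatly improves hyperparameter mixing).
    pg_method : "exact" (Devroye device) or "truncated_series".
    priors : PriorConfig, optional — defaults to the study's settings
        (diffuse normal slopes, InvGamma(1, 1) intercept variance).
    random_state : seed for all chains.

    Attributes
    ----------
    draws_ : PosteriorDraws
    beta_, alpha_, mu_alpha_, sigma_alpha_sq_ : posterior means
    summary_ : FitSummary (means, SDs, 95% intervals, WAIC, R-hat)
    """

    def __init__(
        self,
        n_iter: int = 2000,
        n_burn: int = 500,
        n_chains: int = 2,
        thin: int = 1,
        use_asis: bool = True,
        pg_method: str = "exact",
        series_terms: int = 200,
        priors: PriorConfig | None = None,
        store_log_lik: bool = True,
        random_state: int = 0,
    ):
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.n_chains = n_chains
        self.thin = thin
        self.use_asis = use_asis
        self.pg_method = pg_method
        self.series_terms = series_terms
        self.priors = priors
        self.store_log_lik = store_log_lik
        self.random_state = random_state

    def _sampler_config(self) -> SamplerConfig:
        return SamplerConfig(
            n_iter=self.n_iter,
            n_burn=self.n_burn,
            n_chains=self.n_chains,
            thin=self.thin,
            use_asis=self.use_asis,
            pg_method=self.pg_method,
            series_terms=self.series_terms,
            store_log_lik=self.store_log_lik,
            seed=self.random_state,
        )

    def fit(self, X, y, groups=None, column_names=None):
        """Fit on stacked rows; ``groups`` labels each row's respondent."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if groups is None:
            raise ValueError("groups (respondent identifiers per row) is required")
        data = PanelDataset.from_arrays(y, X, groups, column_names)
        self.data_ = data
        self.classes_ = np.array([0, 1])
        self.draws_ = run_gibbs(data, self.priors, self._sampler_config())
        self.summary_ = summarize(self.draws_)
        self.beta_ = self.draws_.beta.reshape(-1, data.K).mean(axis=0)
        self.alpha_ = self.draws_.alpha.reshape(-1, data.R).mean(axis=0)
        self.mu_alpha_ = float(self.draws_.mu_alpha.mean())
        self.sigma_alpha_sq_ = float(self.draws_.sigma_alpha_sq.mean())
        self.n_features_in_ = data.K
        return self

    def _intercepts(self, n_rows: int, groups) -> np.ndarray:
        lookup = {rid: a for rid, a in zip(self.data_.respondent_ids, self.alpha_)}
        if groups is None:
            return np.full(n_rows, self.mu_alpha_)
        return np.array([lookup.get(g, self.mu_alpha_) for g in np.asarray(groups)])

    def predict_proba(self, X, groups=None) -> np.ndarray:
        """Posterior-mean success probabilities; unseen respondents fall
        back to the population intercept mu_alpha."""
        check_is_fitted(self, "beta_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        psi = self._intercepts(X.shape[0], groups) + X @ self.beta_
        p = np.empty_like(psi)
        pos = psi >= 0
        p[pos] = 1.0 / (1.0 + np.exp(-psi[pos]))
        e = np.exp(psi[~pos])
        p[~pos] = e / (1.0 + e)
        return np.column_stack([1.0 - p, p])

    def predict(self, X, groups=None) -> np.ndarray:
        return (self.predict_proba(X, groups)[:, 1] >= 0.5).astype(int)
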