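"""Posterior summaries, WAIC and split Gelman–Rubin diagnostics.

WAIC is computed on the deviance scale, waic = -2 (lppd - p_waic), from
the stored pointwise log-likelihood matrix; the pointwise terms condition
on the sampled intercepts (conditional WAIC), matching the
per-observation factorization of the Bernoulli likelihood.  Credible
intervals are central (equal-tailed) 95% intervals, and a coefficient is
flagged when its interval excludes zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sampler import PosteriorDraws

__all__ = [
    "compute_waic",
    "gelman_rubin",
    "rhat_all",
    "summarize",
    "FitSummary",
    "ordered_individual_effects",
]


def compute_waic(draws) -> tuple[float, float, float]:
    """(waic, lppd, p_waic) from a draw store or an (S, N) log-lik matrix.

    lppd sums log mean_s exp(ll_si) over observations via a stable
    log-mean-exp; p_waic sums the across-draw sample variances.
    """
    ll = draws.pooled_log_lik() if isinstance(draws, PosteriorDraws) else np.asarray(draws, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws, observations) matrix with at least 2 draws")
    s = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(s)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    waic = -2.0 * (lppd - p_waic)
    return waic, lppd, p_waic


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-half R-hat for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    so convergence failures within a single chain are also visible.
    Returns NaN for degenerate (zero within-sequence variance) draws.
    """
    arr = np.atleast_2d(np.asarray(chains, dtype=float))
    n = arr.shape[1] // 2
    if n < 2:
        raise ValueError("need at least 4 draws per chain to split")
    seqs = np.concatenate([arr[:, :n], arr[:, n : 2 * n]], axis=0)
    w = seqs.var(axis=1, ddof=1).mean()
    b = n * seqs.mean(axis=1).var(ddof=1)
    if w == 0:
        return float("nan")  # degenerate: constant sequences
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def rhat_all(draws: PosteriorDraws) -> dict:
    """Split R-hat for every sampled scalar parameter."""
    return {name: gelman_rubin(arr) for name, arr in draws.iter_parameters()}


@dataclass
class FitSummary:
    """Posterior mean/SD/95% interval table plus fit-level diagnostics."""

    table: pd.DataFrame
    waic: float
    lppd: float
    p_waic: float
    max_rhat: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_json(self, path=None) -> str:
        payload = {
            "waic": self.waic,
            "lppd": self.lppd,
            "p_waic": self.p_waic,
            "max_rhat": self.max_rhat,
            "parameters": json.loads(self.table.to_json(orient="index")),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def summarize(draws: PosteriorDraws, prob: float = 0.95) -> FitSummary:
    """Tables-style posterior summary with significance flags.

    One row per parameter: posterior mean, posterior SD, the central
    ``prob`` interval, whether it excludes zero, and split R-hat.
    """
    lo_q, hi_q = 0.5 - prob / 2, 0.5 + prob / 2
    rows = {}
    for name, arr in draws.iter_parameters():
        pooled = arr.reshape(-1)
        lo, hi = np.quantile(pooled, [lo_q, hi_q])
        rows[name] = {
            "mean": float(pooled.mean()),
            "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
            f"q{100 * lo_q:g}": float(lo),
            f"q{100 * hi_q:g}": float(hi),
            "excludes_zero": bool(lo > 0 or hi < 0),
            "rhat": gelman_rubin(arr) if arr.shape[1] >= 4 else float("nan"),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if draws.log_lik is not None and draws.n_draws * draws.n_chains >= 2:
        waic, lppd, p_waic = compute_waic(draws)
    else:
        waic = lppd = p_waic = float("nan")
    rhats = table["rhat"].to_numpy()
    max_rhat = float(np.nanmax(rhats)) if np.any(np.isfinite(rhats)) else float("nan")
    return FitSummary(table=table, waic=waic, lppd=lppd, p_waic=p_waic, max_rhat=max_rhat)


def ordered_individual_effects(draws: PosteriorDraws) -> pd.DataFrame:
    """Respondent intercepts ordered by posterior mean, with +/- 1
    posterior-SD bands (the individual-effect caterpillar layout)."""
    c, s, r = draws.alpha.shape
    pooled = draws.alpha.reshape(c * s, r)
    means = pooled.mean(axis=0)
    sds = pooled.std(axis=0, ddof=1) if c * s > 1 else np.zeros(r)
    order = np.argsort(means, kind="stable")
    return pd.DataFrame(
        {
            "rank": np.arange(1, r + 1),
            "respondent_id": draws.respondent_ids[order],
            "mean": means[order],
            "lower": means[order] - sds[order],
            "upper": means[order] + sds[order],
        }
    )


def plot_individual_effects(draws: PosteriorDraws, ax=None):
    """Caterpillar plot of ordered intercept posteriors (optional)."""
    import matplotlib.pyplot as plt

    table = ordered_individual_effects(draws)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.fill_between(table["rank"], table["lower"], table["upper"], alpha=0.35, label="±1 posterior SD")
    ax.plot(table["rank"], table["mean"], lw=1.5, label="posterior mean")
    ax.set_xlabel("respondent (ordered)")
    ax.set_ylabel("individual effect")
    ax.legend()
    return ax
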