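"""Synthetic unbalanced-panel survey generator.

The real survey behind this analysis is access-restricted, so every
downstream stage is exercised on simulated tables that reproduce the
structural features the model assumes: R respondents observed over up to
nine annual waves with unbalanced participation, binary outcomes drawn
from the random-intercept logit, covariate blocks shaped like the survey's
descriptive tables, item-level missingness, and planted "degenerate"
respondents (constant responders, short participants, foreign residents)
for exercising the exclusion filters.

A single seed expands into independent substreams per purpose (roles,
participation, effects, covariates, outcomes, missingness) so that, e.g.,
changing the missingness rate leaves the generated outcomes untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .variables import CovariateScheme, DummyBlock, MoneyItem, NormalItem, SatisfactionItem, default_scheme

__all__ = ["DegenerateFractions", "SimConfig", "RawPanelTable", "generate_panel", "inject_missingness"]

ID_COLUMNS = ("respondent_id", "year", "outcome", "residence_country")
HOME_COUNTRY = "Japan"


@dataclass(frozen=True)
class DegenerateFractions:
    """Fractions of respondents planted as filter-triggering cases."""

    all_one: float = 0.0
    all_zero: float = 0.0
    short: float = 0.0
    foreign: float = 0.0

    def __post_init__(self):
        vals = (self.all_one, self.all_zero, self.short, self.foreign)
        if min(vals) < 0 or sum(vals) >= 1:
            raise ValueError("degenerate fractions must be nonnegative and sum to < 1")


@dataclass
class SimConfig:
    """Generative settings for one synthetic panel.

    ``true_beta`` is keyed by design-column name (dummy columns such as
    ``spouse_yes`` or ``year_2015``, or quantitative column names);
    unspecified coefficients are zero.  Participation for regular
    respondents is T_r uniform on {5..9} contiguous waves, matching the
    post-filter regime; planted short respondents get 2-4 waves (two at
    least, so the short and constant-outcome conditions stay disjoint).
    """

    n_respondents: int = 500
    waves: tuple = tuple(range(2014, 2023))
    true_beta: dict = field(default_factory=dict)
    true_mu_alpha: float = 0.0
    true_sigma_alpha: float = 1.0
    covariate_scheme: CovariateScheme | None = None
    missing_rate: float = 0.0
    degenerate_fractions: DegenerateFractions = field(default_factory=DegenerateFractions)
    min_waves: int = 5
    ensure_nonconstant: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.covariate_scheme is None:
            self.covariate_scheme = default_scheme()
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if self.true_sigma_alpha <= 0:
            raise ValueError("true_sigma_alpha must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if isinstance(self.degenerate_fractions, dict):
            self.degenerate_fractions = DegenerateFractions(**self.degenerate_fractions)
        if not (2 <= self.min_waves <= len(self.waves)):
            raise ValueError("min_waves must lie in [2, number of waves]")
        year_cols = {f"year_{w}" for w in self.waves}
        known = set(self.covariate_scheme.design_columns) | year_cols
        unknown = set(self.true_beta) - known
        if unknown:
            raise ValueError(f"true_beta names not in covariate scheme: {sorted(unknown)}")


@dataclass
class RawPanelTable:
    """A simulated long-format survey extract plus its generating truth.

    ``data`` has one row per respondent-wave; ``truth`` one row per
    respondent (its alpha_r, planted role and wave count); ``params``
    records the generating parameter values.
    """

    data: pd.DataFrame
    truth: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def covariate_columns(self) -> list:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(out / "panel.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        (out / "params.json").write_text(json.dumps(self.params, indent=2, default=float))

    @classmethod
    def read(cls, in_dir) -> "RawPanelTable":
        out = Path(in_dir)
        data = pd.read_csv(out / "panel.csv")
        truth = pd.read_csv(out / "truth.csv")
        params_file = out / "params.json"
        params = json.loads(params_file.read_text()) if params_file.exists() else {}
        return cls(data, truth, params)


def _logistic(psi: np.ndarray) -> np.ndarray:
    out = np.empty_like(psi)
    pos = psi >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-psi[pos]))
    e = np.exp(psi[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _draw_quantitative(item, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(item, SatisfactionItem):
        vals = np.rint(rng.normal(item.mean, item.sd, size=n))
        return np.clip(vals, -5, 5)
    if isinstance(item, MoneyItem):
        raw = np.exp(rng.normal(item.log_mean, item.log_sd, size=n))
        raw[rng.random(n) < item.zero_prob] = 0.0
        return np.log1p(raw)
    if isinstance(item, NormalItem):
        return rng.normal(item.mean, item.sd, size=n)
    raise TypeError(f"unknown quantitative item {item!r}")


def generate_panel(config: SimConfig) -> RawPanelTable:
    """Simulate one survey table from the random-intercept logit model."""
    scheme = config.covariate_scheme
    n = config.n_respondents
    waves = np.asarray(config.waves)
    n_waves = len(waves)
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_roles, rng_part, rng_eff, rng_cov, rng_out, rng_miss = (np.random.default_rng(s) for s in streams)

    # ---- planted roles (disjoint by construction) ----
    frac = config.degenerate_fractions
    counts = {k: int(round(getattr(frac, k) * n)) for k in ("all_one", "all_zero", "short", "foreign")}
    if sum(counts.values()) >= n:
        raise ValueError("degenerate counts exhaust the respondent pool")
    perm = rng_roles.permutation(n)
    roles = np.full(n, "none", dtype=object)
    pos = 0
    for role, cnt in counts.items():
        roles[perm[pos : pos + cnt]] = role
        pos += cnt

    # ---- participation: contiguous wave runs ----
    t_r = np.empty(n, dtype=int)
    regular = roles != "short"
    t_r[regular] = rng_part.integers(config.min_waves, n_waves + 1, size=int(regular.sum()))
    t_r[~regular] = rng_part.integers(2, config.min_waves, size=int((~regular).sum()))
    starts = rng_part.integers(0, n_waves - t_r + 1)

    ids = np.array([f"R{i + 1:05d}" for i in range(n)])
    rid = np.repeat(np.arange(n), t_r)
    year = np.concatenate([waves[s : s + t] for s, t in zip(starts, t_r)])
    rt = len(rid)

    # ---- covariates ----
    cov = {}
    for blk in scheme.dummy_blocks:
        if blk.time_varying:
            draws = rng_cov.choice(np.asarray(blk.levels, dtype=object), size=rt, p=blk.probs)
        else:
            per_r = rng_cov.choice(np.asarray(blk.levels, dtype=object), size=n, p=blk.probs)
            draws = per_r[rid]
        cov[blk.name] = draws
    for item in scheme.quantitative:
        cov[item.name] = _draw_quantitative(item, rt, rng_cov)
    cov_frame = pd.DataFrame(cov)

    # ---- linear predictor ----
    design = scheme.encode(cov_frame)
    for w in waves[1:]:
        design[f"year_{w}"] = (year == w).astype(float)
    alpha = rng_eff.normal(config.true_mu_alpha, config.true_sigma_alpha, size=n)
    psi = alpha[rid].copy()
    for name, coef in config.true_beta.items():
        psi += coef * design[name].to_numpy()
    prob = _logistic(psi)

    # ---- outcomes ----
    y = (rng_out.random(rt) < prob).astype(int)
    block_start = np.r_[0, np.cumsum(t_r)[:-1]]
    for i in range(n):
        sl = slice(block_start[i], block_start[i] + t_r[i])
        if roles[i] == "all_one":
            y[sl] = 1
        elif roles[i] == "all_zero":
            y[sl] = 0
        elif config.ensure_nonconstant and t_r[i] >= 2:
            p = prob[sl]
            for _ in range(500):
                if 0 < y[sl].sum() < t_r[i]:
                    break
                y[sl] = (rng_out.random(t_r[i]) < p).astype(int)
            else:  # pragma: no cover - pathological probabilities
                j = int(np.argmin(np.abs(p - 0.5)))
                y[block_start[i] + j] = 1 - y[block_start[i] + j]

    # ---- residence ----
    residence = np.full(rt, HOME_COUNTRY, dtype=object)
    for i in np.flatnonzero(roles == "foreign"):
        j = rng_roles.integers(t_r[i])
        residence[block_start[i] + int(j)] = "Abroad"

    data = pd.DataFrame({"respondent_id": ids[rid], "year": year, "outcome": y, "residence_country": residence})
    data = pd.concat([data, cov_frame], axis=1)

    truth = pd.DataFrame({"respondent_id": ids, "alpha": alpha, "planted": roles, "n_waves": t_r})
    params = {
        "n_respondents": n,
        "waves": [int(w) for w in waves],
        "true_beta": dict(config.true_beta),
        "true_mu_alpha": config.true_mu_alpha,
        "true_sigma_alpha": config.true_sigma_alpha,
        "missing_rate": config.missing_rate,
        "degenerate_fractions": asdict(config.degenerate_fractions),
        "seed": config.seed,
    }
    table = RawPanelTable(data, truth, params)
    if config.missing_rate > 0:
        miss_seed = int(streams[5].generate_state(1)[0] % (2**31))
        table = inject_missingness(table, config.missing_rate, seed=miss_seed)
    return table


def inject_missingness(table, rate: float, seed: int):
    """Blank each covariate cell independently with probability ``rate``.

    Outcome, identifiers, year and residence are never blanked.  Accepts a
    :class:`RawPanelTable` or a bare data frame and returns the same type.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    frame = table.data if isinstance(table, RawPanelTable) else table
    out = frame.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        cols = [c for c in out.columns if c not in ID_COLUMNS]
        mask = rng.random((len(out), len(cols))) < rate
        for j, c in enumerate(cols):
            if out[c].dtype.kind in "iub":
                out[c] = out[c].astype(float)
            out.loc[mask[:, j], c] = np.nan
    if isinstance(table, RawPanelTable):
        return RawPanelTable(out, table.truth.copy(), dict(table.params))
    return out
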