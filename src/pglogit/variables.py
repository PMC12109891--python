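"""Covariate vocabulary shared by the simulator and the design builder.

The survey's explanatory variables fall into dummy blocks (spouse, sex,
survey year, age band, region of residence, city size) and quantitative
blocks (seven life-satisfaction items on a centred -5..+5 scale and 22
monetary items stored on a log1p scale).  The default scheme mirrors the
survey's marginal shapes; ``simple_scheme`` gives plain Gaussian
covariates for methodological simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DummyBlock",
    "SatisfactionItem",
    "MoneyItem",
    "NormalItem",
    "CovariateScheme",
    "default_scheme",
    "simple_scheme",
    "model_covariates",
    "STRATA",
    "MODEL_IDS",
]

STRATA = ("all", "married_men", "married_women", "unmarried_men", "unmarried_women")
MODEL_IDS = (1, 2, 3, 4)


@dataclass(frozen=True)
class DummyBlock:
    """A categorical survey variable coded 0/1 against its first (reference) level."""

    name: str
    levels: tuple
    probs: tuple
    time_varying: bool = True

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValueError(f"dummy block {self.name!r}: needs >= 2 levels")
        if len(self.probs) != len(self.levels):
            raise ValueError(f"dummy block {self.name!r}: probs/levels length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-8 or min(self.probs) < 0:
            raise ValueError(f"dummy block {self.name!r}: probs must be a distribution")

    @property
    def reference(self):
        return self.levels[0]

    @property
    def design_columns(self) -> list[str]:
        return [f"{self.name}_{lvl}" for lvl in self.levels[1:]]


@dataclass(frozen=True)
class SatisfactionItem:
    """Centred satisfaction score: integer scale from -5 (dissatisfied) to +5."""

    name: str
    mean: float = 0.0
    sd: float = 2.3


@dataclass(frozen=True)
class MoneyItem:
    """Monetary amount, stored as log(1 + raw); raw is zero-inflated log-normal."""

    name: str
    zero_prob: float = 0.3
    log_mean: float = 5.0
    log_sd: float = 1.0


@dataclass(frozen=True)
class NormalItem:
    """Plain Gaussian covariate (for methodological simulations)."""

    name: str
    mean: float = 0.0
    sd: float = 1.0


@dataclass(frozen=True)
class CovariateScheme:
    dummy_blocks: tuple = ()
    quantitative: tuple = ()

    def __post_init__(self):
        names = [b.name for b in self.dummy_blocks] + [q.name for q in self.quantitative]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names in scheme")
        for blk in self.dummy_blocks:
            if len(set(blk.levels)) != len(blk.levels):
                raise ValueError(f"dummy block {blk.name!r}: duplicate levels")

    @property
    def raw_columns(self) -> list[str]:
        return [b.name for b in self.dummy_blocks] + [q.name for q in self.quantitative]

    @property
    def design_columns(self) -> list[str]:
        cols: list[str] = []
        for blk in self.dummy_blocks:
            cols.extend(blk.design_columns)
        cols.extend(q.name for q in self.quantitative)
        return cols

    def block_of(self, raw_column: str):
        for blk in self.dummy_blocks:
            if blk.name == raw_column:
                return blk
        for q in self.quantitative:
            if q.name == raw_column:
                return q
        raise KeyError(raw_column)

    def encode(self, frame: pd.DataFrame) -> pd.DataFrame:
        """One-hot encode dummy blocks against their reference level.

        Quantitative columns pass through unchanged.  Unknown category
        levels raise, naming the offending entry.
        """
        out = {}
        for blk in self.dummy_blocks:
            col = frame[blk.name]
            bad = set(col.dropna().unique()) - set(blk.levels)
            if bad:
                raise ValueError(f"unknown level(s) {sorted(map(str, bad))} in dummy block {blk.name!r}")
            for lvl in blk.levels[1:]:
                out[f"{blk.name}_{lvl}"] = (col == lvl).astype(float)
        for q in self.quantitative:
            out[q.name] = frame[q.name].astype(float)
        return pd.DataFrame(out, index=frame.index)

    def decode_dummies(self, design: pd.DataFrame) -> pd.DataFrame:
        """Inverse of :meth:`encode` for the dummy blocks (round-trip check)."""
        out = {}
        for blk in self.dummy_blocks:
            cols = [f"{blk.name}_{lvl}" for lvl in blk.levels[1:]]
            sub = design[cols].to_numpy()
            level = np.full(len(design), blk.reference, dtype=object)
            for j, lvl in enumerate(blk.levels[1:]):
                level[sub[:, j] == 1.0] = lvl
            out[blk.name] = level
        return pd.DataFrame(out, index=design.index)


# --- default scheme: marginals shaped like the survey's descriptive tables ---

_SAT_ITEMS = [
    ("sat_household_income", -0.386, 2.458),
    ("sat_employment", 0.157, 2.336),
    ("sat_housing", 0.939, 2.328),
    ("sat_leisure_time", 0.582, 2.349),
    ("sat_leisure_activities", 0.547, 2.208),
    ("sat_health", 0.478, 2.198),
    ("sat_life_overall", 0.798, 1.931),
]

# (name, zero_prob, log_mean, log_sd) chosen to echo the published medians
# and spreads of the log1p-scale amounts; no joint structure is claimed.
_MONEY_ITEMS = [
    ("fin_savings", 0.25, 5.9, 1.5),
    ("fin_securities", 0.70, 5.5, 1.5),
    ("fin_borrowings", 0.60, 6.0, 1.5),
    ("fin_household_income", 0.02, 6.3, 0.7),
    ("fin_asset_income", 0.75, 3.5, 1.5),
    ("inc_self_salary", 0.20, 5.9, 1.2),
    ("inc_self_investment", 0.75, 3.5, 1.5),
    ("inc_self_other", 0.45, 4.0, 1.5),
    ("inc_spouse_salary", 0.55, 5.0, 1.5),
    ("inc_spouse_investment", 0.90, 3.0, 1.2),
    ("inc_spouse_other", 0.65, 3.5, 1.5),
    ("inc_family_other", 0.55, 5.0, 1.5),
    ("cons_food", 0.01, 4.3, 0.5),
    ("cons_rent_repairs", 0.60, 4.5, 1.5),
    ("cons_furniture", 0.55, 3.0, 1.2),
    ("cons_clothing", 0.20, 2.4, 1.0),
    ("cons_education_leisure", 0.25, 2.4, 1.2),
    ("cons_other", 0.01, 4.7, 0.8),
    ("exp_loan_repayments", 0.65, 2.5, 1.0),
    ("exp_donations", 0.65, 5.0, 2.0),
    ("asset_house", 0.40, 7.0, 1.3),
    ("asset_plot", 0.40, 7.3, 1.2),
]


def default_scheme() -> CovariateScheme:
    """Scheme mirroring the survey's variable blocks and marginal shapes."""
    dummies = (
        DummyBlock("spouse", ("no", "yes"), (0.254, 0.746)),
        DummyBlock("sex", ("female", "male"), (0.509, 0.491), time_varying=False),
        DummyBlock(
            "age",
            ("under40", "40_49", "50_59", "60_69", "70plus"),
            (0.110, 0.216, 0.226, 0.222, 0.226),
        ),
        DummyBlock(
            "region",
            ("kanto", "hokkaido", "tohoku", "chubu", "kinki", "chugoku", "shikoku", "kyushu"),
            (0.3305, 0.0478, 0.0642, 0.1759, 0.1844, 0.0626, 0.0271, 0.1075),
            time_varying=False,
        ),
        DummyBlock("city", ("major", "other", "town_village"), (0.2998, 0.6064, 0.0938)),
    )
    quant = tuple(SatisfactionItem(n, m, s) for n, m, s in _SAT_ITEMS) + tuple(
        MoneyItem(n, p0, lm, ls) for n, p0, lm, ls in _MONEY_ITEMS
    )
    return CovariateScheme(dummy_blocks=dummies, quantitative=quant)


def simple_scheme(k: int) -> CovariateScheme:
    """``k`` independent standard-normal covariates (no dummy blocks)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return CovariateScheme(quantitative=tuple(NormalItem(f"x{j + 1}") for j in range(k)))


_SAT_COLS = [n for n, *_ in _SAT_ITEMS]
_FINANCE_COLS = [n for n, *_ in _MONEY_ITEMS]
_SPOUSE_INCOME_COLS = ["inc_spouse_salary", "inc_spouse_investment", "inc_spouse_other"]


def _year_columns(waves) -> list[str]:
    return [f"year_{w}" for w in list(waves)[1:]]


def model_covariates(model_id: int, stratum: str = "all", waves=range(2014, 2023)) -> list[str]:
    """Ordered design columns for one of the four model specifications.

    All models carry the year, age band, region and city-size controls.
    Model 1 adds the satisfaction and household-finance blocks, Model 2
    the satisfaction block only, Model 3 the finance block only, Model 4
    neither.  The spouse and sex dummies enter only the pooled stratum
    (within a marital-status x gender stratum they are constant), and the
    spouse-income items are dropped in the unmarried strata where they
    are structurally zero.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"model_id must be one of {MODEL_IDS}, got {model_id}")
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}, got {stratum!r}")
    cols: list[str] = []
    if stratum == "all":
        cols += ["spouse_yes", "sex_male"]
    cols += _year_columns(waves)
    cols += ["age_40_49", "age_50_59", "age_60_69", "age_70plus"]
    cols += [f"region_{r}" for r in ("hokkaido", "tohoku", "chubu", "kinki", "chugoku", "shikoku", "kyushu")]
    cols += ["city_other", "city_town_village"]
    if model_id in (1, 2):
        cols += _SAT_COLS
    if model_id in (1, 3):
        fin = list(_FINANCE_COLS)
        if stratum in ("unmarried_men", "unmarried_women"):
            fin = [c for c in fin if c not in _SPOUSE_INCOME_COLS]
        cols += fin
    return cols
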