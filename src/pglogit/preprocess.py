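"""Respondent filtering, k-NN imputation and design-matrix construction.

Random-intercept logit estimation needs a stable run of responses per
respondent, and a respondent whose binary outcome never varies carries no
information about their intercept.  Respondents are therefore excluded if
they meet any of

* Condition 1 — fewer than five responses,
* Condition 2 — all responses ones or all zeros,
* Condition 3 — residing outside Japan in any wave.

Filtering happens before imputation: all three conditions depend only on
always-observed fields, so rows destined for removal are never imputed.

Missing covariate cells are completed by a k-nearest-neighbour rule: the
mean (quantitative) or mode (categorical) of the k nearest fully-complete
rows under standardized Euclidean distance, with categorical mismatches
contributing like one-hot coordinates.  Ties in distance break toward the
lowest row index so the procedure is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import PanelDataset
from .simulate import HOME_COUNTRY, ID_COLUMNS, RawPanelTable
from .variables import CovariateScheme, MODEL_IDS, STRATA, default_scheme, model_covariates

__all__ = ["FilterReport", "apply_filters", "PanelKNNImputer", "impute_knn", "ModelSpec", "build_design"]


@dataclass
class FilterReport:
    """Tally of the respondent exclusions, per condition and overall."""

    n_rows_in: int
    n_rows_out: int
    n_respondents_in: int
    n_respondents_out: int
    removed_by_condition: dict
    removed_ids: dict

    def to_json(self, path=None) -> str:
        payload = {
            "n_rows_in": self.n_rows_in,
            "n_rows_out": self.n_rows_out,
            "n_respondents_in": self.n_respondents_in,
            "n_respondents_out": self.n_respondents_out,
            "removed_by_condition": self.removed_by_condition,
            "removed_ids": {k: list(map(str, v)) for k, v in self.removed_ids.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _as_frame(table) -> pd.DataFrame:
    return table.data if isinstance(table, RawPanelTable) else table


def apply_filters(table):
    """Drop respondents tripping any exclusion condition.

    Returns the filtered object (same type as the input) and a
    :class:`FilterReport`.  A respondent may trip several conditions and
    appears in each tally, but is removed once.
    """
    frame = _as_frame(table)
    required = {"respondent_id", "outcome"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ValueError(f"table lacks required columns: {sorted(missing_cols)}")
    if frame["outcome"].isna().any():
        raise ValueError("outcome contains missing values; the response must be complete before filtering")

    grp = frame.groupby("respondent_id", sort=False)
    counts = grp["outcome"].size()
    sums = grp["outcome"].sum()
    cond1 = counts.index[counts < 5]
    cond2 = counts.index[(sums == 0) | (sums == counts)]
    if "residence_country" in frame.columns:
        abroad = grp["residence_country"].apply(lambda s: (s != HOME_COUNTRY).any())
        cond3 = abroad.index[abroad]
    else:
        cond3 = pd.Index([])

    removed_ids = {1: list(cond1), 2: list(cond2), 3: list(cond3)}
    removed = set(cond1) | set(cond2) | set(cond3)
    keep = ~frame["respondent_id"].isin(removed)
    out = frame.loc[keep].reset_index(drop=True)
    report = FilterReport(
        n_rows_in=len(frame),
        n_rows_out=len(out),
        n_respondents_in=int(counts.size),
        n_respondents_out=int(counts.size - len(removed)),
        removed_by_condition={k: len(v) for k, v in removed_ids.items()},
        removed_ids=removed_ids,
    )
    if isinstance(table, RawPanelTable):
        truth = table.truth[~table.truth["respondent_id"].isin(removed)].reset_index(drop=True)
        return RawPanelTable(out, truth, dict(table.params)), report
    return out, report


class PanelKNNImputer(TransformerMixin, BaseEstimator):
    """Impute missing covariate cells from the k nearest complete rows.

    Distances are standardized Euclidean over ``distance_columns``
    (defaulting to every covariate column), restricted to the coordinates
    observed in the query row; categorical columns contribute a squared
    distance of 2 per mismatch (one-hot geometry).  Quantitative cells take
    the neighbour mean, categorical cells the neighbour mode (mode ties
    break toward the nearest neighbour holding a tied value).  Observed
    cells are never altered and the outcome is never imputed.
    """

    def __init__(self, k: int = 5, distance_columns=None):
        self.k = k
        self.distance_columns = distance_columns

    def fit(self, X: pd.DataFrame, y=None):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        frame = _as_frame(X)
        self.covariate_columns_ = [c for c in frame.columns if c not in ID_COLUMNS]
        if not self.covariate_columns_:
            raise ValueError("no covariate columns to impute")
        cols = self.distance_columns
        if cols is None:
            cols = self.covariate_columns_
        unknown = set(cols) - set(self.covariate_columns_)
        if unknown:
            raise ValueError(f"distance_columns not in table: {sorted(unknown)}")
        self.distance_columns_ = list(cols)
        sub = frame[self.covariate_columns_]
        for c in self.covariate_columns_:
            if sub[c].isna().all():
                raise ValueError(f"column {c!r} is entirely missing; cannot impute")
        complete = sub.notna().all(axis=1)
        if int(complete.sum()) < self.k:
            worst = sub.isna().sum().idxmax()
            raise ValueError(
                f"only {int(complete.sum())} complete rows for k={self.k} "
                f"(most-missing column: {worst!r})"
            )
        self.reference_ = frame.loc[complete, self.covariate_columns_].reset_index(drop=True)
        self.numeric_dist_cols_ = [
            c for c in self.distance_columns_ if pd.api.types.is_numeric_dtype(frame[c])
        ]
        self.categorical_dist_cols_ = [c for c in self.distance_columns_ if c not in self.numeric_dist_cols_]
        means, sds = {}, {}
        for c in self.numeric_dist_cols_:
            col = frame[c].astype(float)
            means[c] = float(col.mean())
            sd = float(col.std(ddof=0))
            sds[c] = sd if sd > 0 else 1.0
        self.scale_mean_, self.scale_sd_ = means, sds
        return self

    def transform(self, X) -> pd.DataFrame:
        frame = _as_frame(X).copy().reset_index(drop=True)
        ref = self.reference_
        ref_num = {
            c: (ref[c].astype(float).to_numpy() - self.scale_mean_[c]) / self.scale_sd_[c]
            for c in self.numeric_dist_cols_
        }
        ref_cat = {c: ref[c].to_numpy() for c in self.categorical_dist_cols_}
        covs = [c for c in self.covariate_columns_ if c in frame.columns]
        incomplete = frame[covs].isna().any(axis=1)
        for i in np.flatnonzero(incomplete.to_numpy()):
            row = frame.loc[i]
            d2 = np.zeros(len(ref))
            for c in self.numeric_dist_cols_:
                v = row[c]
                if pd.isna(v):
                    continue
                z = (float(v) - self.scale_mean_[c]) / self.scale_sd_[c]
                d2 += (ref_num[c] - z) ** 2
            for c in self.categorical_dist_cols_:
                v = row[c]
                if pd.isna(v):
                    continue
                d2 += 2.0 * (ref_cat[c] != v)
            order = np.argsort(d2, kind="stable")[: self.k]
            for c in covs:
                if not pd.isna(row[c]):
                    continue
                neigh = ref[c].to_numpy()[order]
                if pd.api.types.is_numeric_dtype(ref[c]):
                    frame.at[i, c] = float(np.mean(neigh.astype(float)))
                else:
                    vals, cnts = np.unique(neigh, return_counts=True)
                    tied = set(vals[cnts == cnts.max()])
                    for v in neigh:  # nearest neighbour holding a tied value
                        if v in tied:
                            frame.at[i, c] = v
                            break
        if isinstance(X, RawPanelTable):
            return RawPanelTable(frame, X.truth.copy(), dict(X.params))
        return frame


def impute_knn(table, k: int = 5, distance_columns=None):
    """Functional wrapper: fit the imputer on the table and complete it."""
    imp = PanelKNNImputer(k=k, distance_columns=distance_columns)
    return imp.fit(table).transform(table)


@dataclass
class ModelSpec:
    """One fitted cell of the experimental grid.

    ``model_id`` 1-4 selects the covariate blocks; ``stratum`` restricts
    the sample by (modal) marital status and gender.  ``covariate_names``
    may be supplied explicitly for non-survey designs (``model_id`` is
    then just a label).
    """

    model_id: int | str = 1
    stratum: str = "all"
    covariate_names: list = field(default_factory=list)
    waves: tuple = tuple(range(2014, 2023))

    def __post_init__(self):
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}, got {self.stratum!r}")
        if not self.covariate_names:
            if self.model_id not in MODEL_IDS:
                raise ValueError("explicit covariate_names required for non-standard model_id")
            self.covariate_names = model_covariates(self.model_id, self.stratum, self.waves)

    @property
    def label(self) -> str:
        return f"model{self.model_id}_{self.stratum}"


def _modal_spouse(series: pd.Series) -> str:
    """Majority spouse status over a respondent's waves; ties -> married."""
    n_yes = int((series == "yes").sum())
    return "yes" if 2 * n_yes >= len(series) else "no"


def build_design(
    table,
    spec: ModelSpec,
    scheme: CovariateScheme | None = None,
    *,
    raw_money: bool = False,
    drop_zero_variance: bool = False,
) -> PanelDataset:
    """Assemble (y, X) for one model specification.

    The table must already be filtered and complete.  Dummy blocks are
    coded 0/1 against their reference levels, satisfaction items pass
    through on the centred scale, and monetary amounts are assumed to be
    on the log1p scale already unless ``raw_money`` requests the
    log(1 + raw) transform here.  Rows are restricted to ``spec.stratum``
    and columns ordered per ``spec.covariate_names``.
    """
    frame = _as_frame(table).copy()
    if scheme is None:
        scheme = default_scheme()
    cov_cols = [c for c in frame.columns if c not in ID_COLUMNS]
    if frame[cov_cols + ["outcome"]].isna().any().any():
        raise ValueError("table contains missing values; impute before building the design")
    frame = frame.sort_values(["respondent_id", "year"], kind="stable").reset_index(drop=True)

    if spec.stratum != "all":
        for needed in ("spouse", "sex"):
            if needed not in frame.columns:
                raise ValueError(f"stratified spec needs a {needed!r} column")
        modal = frame.groupby("respondent_id", sort=False)["spouse"].agg(_modal_spouse)
        sex = frame.groupby("respondent_id", sort=False)["sex"].first()
        married = modal == "yes"
        male = sex == "male"
        masks = {
            "married_men": married & male,
            "married_women": married & ~male,
            "unmarried_men": ~married & male,
            "unmarried_women": ~married & ~male,
        }
        wanted = masks[spec.stratum]
        frame = frame[frame["respondent_id"].map(wanted)].reset_index(drop=True)
        if frame.empty:
            raise ValueError(f"stratum {spec.stratum!r} contains no respondents")

    if raw_money:
        money_names = {q.name for q in scheme.quantitative if hasattr(q, "zero_prob")}
        for c in money_names & set(frame.columns):
            frame[c] = np.log1p(frame[c].astype(float))

    design = scheme.encode(frame[[c for c in scheme.raw_columns if c in frame.columns]])
    if "year" in frame.columns:
        for w in spec.waves[1:]:
            design[f"year_{w}"] = (frame["year"] == w).astype(float)

    missing = [c for c in spec.covariate_names if c not in design.columns]
    if missing:
        raise ValueError(f"spec requires columns absent from the table: {missing}")
    cols = list(spec.covariate_names)
    if drop_zero_variance:
        keep = [c for c in cols if design[c].nunique() > 1]
        cols = keep
    X = design[cols].to_numpy(dtype=float)
    y = frame["outcome"].to_numpy(dtype=float)
    rid_labels = frame["respondent_id"].to_numpy()
    ids = pd.unique(rid_labels)
    order = {g: i for i, g in enumerate(ids)}
    ridx = np.array([order[g] for g in rid_labels], dtype=np.intp)
    return PanelDataset(y, X, ridx, ids, cols)
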