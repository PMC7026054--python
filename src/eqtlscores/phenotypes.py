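"""Subject-level QC and PCA-derived latent tract phenotypes.

Two exclusion steps mirror the study design: flagged subjects (relatedness or
overlap with discovery cohorts) are removed first, then subjects whose global
measure lies more than three standard deviations from the sample mean are removed
in a single, non-iterative pass, separately for FA and MD (so the FA and MD
analysis samples may differ in size).

Latent phenotypes (global plus the three tract categories) are the scores of the
first unrotated principal component over the relevant tract variables, computed on
the correlation (standardized) scale with the component sign fixed so the mean
loading is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .atlas import NO_HEMISPHERE, TractAtlas, variable_name

logger = logging.getLogger(__name__)

__all__ = [
    "LatentPhenotype",
    "SDOutlierFilter",
    "FirstPCPhenotype",
    "exclude_flagged",
    "exclude_outliers",
    "pivot_wide",
    "derive_latent",
    "derive_all_latents",
    "hemisphere_long_format",
    "LATENT_NAMES",
]

LATENT_NAMES = ("global", "association", "thalamic", "projection")


@dataclass(frozen=True)
class LatentPhenotype:
    """First-principal-component summary of a tract set for one measure."""

    name: str
    measure: str
    scores: pd.Series  # indexed by subject_id
    loadings: pd.Series  # indexed by tract variable name, unit norm
    explained_variance_ratio: float


def exclude_flagged(subject_ids, flags: pd.Series) -> list[str]:
    """Remove subjects whose exclusion flag is set.

    ``flags`` must cover every subject id; flags for unknown subjects raise, to
    catch id mismatches early.
    """
    subject_ids = list(subject_ids)
    unknown = set(flags.index) - set(subject_ids)
    if unknown:
        raise KeyError(f"exclusion flags refer to unknown subject ids: {sorted(unknown)[:5]}")
    missing = set(subject_ids) - set(flags.index)
    if missing:
        raise KeyError(f"exclusion flags missing for subjects: {sorted(missing)[:5]}")
    retained = [s for s in subject_ids if not bool(flags.loc[s])]
    logger.info("flag exclusion removed %d of %d subjects", len(subject_ids) - len(retained),
                len(subject_ids))
    return retained


def exclude_outliers(global_values: pd.Series, k: float = 3.0) -> pd.Index:
    """Subjects within k standard deviations of the sample mean of a global measure.

    A single pass by design: the mean and SD are computed once over all subjects
    and not recomputed after removal. With zero sample SD no subject is excluded
    (a warning is logged).
    """
    if len(global_values) < 2:
        raise ValueError("outlier exclusion needs at least 2 subjects")
    mean = global_values.mean()
    sd = global_values.std(ddof=0)
    if sd == 0.0:
        logger.warning("global measure has zero variance; no outlier exclusions applied")
        return global_values.index
    keep = (global_values - mean).abs() <= k * sd
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("outlier exclusion removed %d of %d subjects", n_drop, len(global_values))
    return global_values.index[keep]


class SDOutlierFilter(TransformerMixin, BaseEstimator):
    """Single-pass +/- k SD exclusion as a fitted transformer.

    ``fit`` stores the sample mean and SD; ``transform`` filters rows using those
    frozen statistics, so refitting is required to change the exclusion rule.
    """

    def __init__(self, k: float = 3.0):
        self.k = k

    def fit(self, X: pd.Series, y=None):
        X = pd.Series(X)
        self.mean_ = float(X.mean())
        self.sd_ = float(X.std(ddof=0))
        return self

    def get_support(self, X: pd.Series) -> pd.Series:
        if self.sd_ == 0.0:
            return pd.Series(True, index=pd.Series(X).index)
        return (pd.Series(X) - self.mean_).abs() <= self.k * self.sd_

    def transform(self, X: pd.Series) -> pd.Series:
        X = pd.Series(X)
        return X[self.get_support(X)]


def pivot_wide(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Subject x tract-variable wide table for one measure.

    Columns are canonical variable names (``tract`` or ``tract_hemisphere``).
    """
    sub = table.loc[table["measure"] == measure].copy()
    sub["variable"] = [
        variable_name(t, h) for t, h in zip(sub["tract_id"], sub["hemisphere"])
    ]
    wide = sub.pivot(index="subject_id", columns="variable", values="value")
    wide.columns.name = None
    return wide


class FirstPCPhenotype(TransformerMixin, BaseEstimator):
    """First unrotated principal component over standardized tract variables.

    Columns are mean-centered and scaled to unit variance before the
    decomposition (PCA on the correlation scale), and the component sign is
    fixed so the mean loading is positive. ``transform`` returns the subject
    scores of that single component.

    Attributes
    ----------
    loadings_ : Series
        Unit-norm PC1 loadings, indexed by column name.
    explained_variance_ratio_ : float
        Fraction of total (standardized) variance carried by PC1.
    """

    def __init__(self, standardize_scores: bool = True):
        self.standardize_scores = standardize_scores

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValueError("FirstPCPhenotype requires complete cases")
        if X.shape[0] < X.shape[1]:
            raise ValueError(
                f"need at least as many subjects ({X.shape[0]}) as variables ({X.shape[1]})"
            )
        self.columns_ = list(X.columns)
        self.mean_ = X.mean(axis=0).to_numpy()
        sd = X.std(axis=0, ddof=0).to_numpy()
        if np.any(sd == 0.0):
            bad = [c for c, s in zip(self.columns_, sd) if s == 0.0]
            raise ValueError(f"zero-variance tract variable(s): {bad}")
        self.scale_ = sd
        Z = (X.to_numpy() - self.mean_) / self.scale_
        pca = PCA(n_components=1, svd_solver="full")
        pca.fit(Z)
        loadings = pca.components_[0]
        if loadings.mean() < 0:  # fix the arbitrary PCA sign
            loadings = -loadings
        self.loadings_ = pd.Series(loadings, index=self.columns_)
        self.explained_variance_ratio_ = float(pca.explained_variance_ratio_[0])
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        X = pd.DataFrame(X)[self.columns_]
        Z = (X.to_numpy() - self.mean_) / self.scale_
        scores = Z @ self.loadings_.to_numpy()
        if self.standardize_scores:
            sd = scores.std()
            scores = (scores - scores.mean()) / (sd if sd > 0 else 1.0)
        return pd.Series(scores, index=X.index, name="pc1")


def derive_latent(
    table: pd.DataFrame,
    tract_variables: list[str],
    measure: str,
    name: str = "latent",
) -> LatentPhenotype:
    """First-unrotated-component latent phenotype over a tract-variable subset.

    Subjects with any missing value in the subset are dropped (and logged).
    """
    wide = pivot_wide(table, measure)
    missing_cols = [v for v in tract_variables if v not in wide.columns]
    if missing_cols:
        raise KeyError(f"tract variables absent from the table: {missing_cols}")
    wide = wide[tract_variables]
    complete = wide.dropna()
    if len(complete) < len(wide):
        logger.info(
            "latent %s (%s): dropped %d incomplete subject(s)",
            name, measure, len(wide) - len(complete),
        )
    est = FirstPCPhenotype().fit(complete)
    return LatentPhenotype(
        name=name,
        measure=measure,
        scores=est.transform(complete),
        loadings=est.loadings_,
        explained_variance_ratio=est.explained_variance_ratio_,
    )


def derive_all_latents(
    table: pd.DataFrame, atlas: TractAtlas, measure: str
) -> dict[str, LatentPhenotype]:
    """Global (all 27 variables) plus per-category latent phenotypes."""
    out = {"global": derive_latent(table, atlas.variable_names(), measure, name="global")}
    for cat in ("association", "thalamic", "projection"):
        out[cat] = derive_latent(
            table, atlas.variable_names(cat), measure, name=cat
        )
    return out


def hemisphere_long_format(
    table: pd.DataFrame,
    tract_id: str,
    measure: str,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two rows per subject (left, right) for one bilateral tract and measure.

    Subjects missing either hemisphere are dropped (logged). If ``covariates``
    is given (indexed by subject id), covariate columns are replicated onto both
    rows. Raises for unilateral tracts, which belong on the linear-model path.
    """
    sub = table.loc[(table["tract_id"] == tract_id) & (table["measure"] == measure)]
    if sub.empty:
        raise KeyError(f"no rows for tract {tract_id!r}, measure {measure!r}")
    if (sub["hemisphere"] == NO_HEMISPHERE).any():
        raise ValueError(
            f"tract {tract_id!r} is unilateral; use the linear-model path instead"
        )
    wide = sub.pivot(index="subject_id", columns="hemisphere", values="value")
    complete = wide.dropna()
    if len(complete) < len(wide):
        logger.info(
            "tract %s (%s): dropped %d subject(s) missing a hemisphere",
            tract_id, measure, len(wide) - len(complete),
        )
    long = complete.reset_index().melt(
        id_vars="subject_id", var_name="hemisphere", value_name="value"
    )
    long = long.sort_values(["subject_id", "hemisphere"], kind="mergesort").reset_index(drop=True)
    if covariates is not None:
        long = long.join(covariates, on="subject_id", validate="many_to_one")
    return long
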