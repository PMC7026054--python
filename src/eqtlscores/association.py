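"""Association models linking eQTL scores to white-matter phenotypes.

Every (score, phenotype) pair is modelled separately, with the full covariate set:
age, age squared, sex, fifteen genetic principal components, three head-position
coordinates, scanner site and genotype array (categorical covariates treatment-
coded against their first level).

* Unilateral tracts and the global/category latent phenotypes use ordinary least
  squares (``fit_linear``); a Frisch-Waugh residualization scan (``linear_scan``)
  computes the identical statistics for whole score-by-phenotype families at once.
* Bilateral tracts use a linear mixed model with a per-subject random intercept
  and hemisphere as a within-subject fixed effect (``fit_bilateral_mixed``),
  estimated by REML.
* ``fit_quadratic`` adds the squared (centered) score to test non-linearity and
  reports the extra variance it explains.
* ``fdr_correct`` applies Benjamini-Hochberg adjustment within each test family
  separately and flags q < 0.05.

Reported effect sizes are standardized: scores and phenotypes are z-scored before
modelling, so a coefficient of 0.04 means 0.04 phenotype SDs per score SD.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "QuadraticResult",
    "covariate_design",
    "fit_linear",
    "fit_bilateral_mixed",
    "fit_quadratic",
    "linear_scan",
    "bh_adjust",
    "fdr_correct",
    "overlap_comparison",
    "results_to_frame",
]

_TINY_P = np.finfo(float).tiny

#: numeric covariates entering every model
NUMERIC_COVARIATES = (
    ["age", "age_squared", "sex"]
    + [f"pc{k}" for k in range(1, 16)]
    + ["pos_x", "pos_y", "pos_z"]
)
#: categorical covariates, treatment-coded with the first level as reference
CATEGORICAL_COVARIATES = ("site", "array")


@dataclass(frozen=True)
class AssociationResult:
    score_id: str
    phenotype: str
    measure: str
    model: str  # "linear" or "mixed_bilateral"
    effect: float
    se: float
    t: float
    p: float
    q: float | None = None
    r2_increment_pct: float | None = None
    n_subjects: int = 0
    converged: bool = True

    @property
    def significant(self) -> bool | None:
        return None if self.q is None else bool(self.q < 0.05)


@dataclass(frozen=True)
class QuadraticResult:
    score_id: str
    phenotype: str
    measure: str
    r2_quadratic_pct: float
    p_quadratic: float


def covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix (without intercept) for the standard covariate set.

    ``age_squared`` is recomputed from ``age`` if absent; site and array are
    expanded into treatment-coded indicator columns against their first level.
    """
    cov = covariates.copy()
    if "age_squared" not in cov.columns and "age" in cov.columns:
        cov["age_squared"] = cov["age"] ** 2
    parts = []
    for c in NUMERIC_COVARIATES:
        if c in cov.columns:
            parts.append(cov[c].astype(float))
    for c in CATEGORICAL_COVARIATES:
        if c in cov.columns:
            dummies = pd.get_dummies(
                cov[c].astype("category"), prefix=c, drop_first=True, dtype=float
            )
            parts.append(dummies)
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing values in covariates: {bad}")
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    """Raise naming the offending column if the design is rank-deficient."""
    A = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) == A.shape[1]:
        return
    for j, col in enumerate(X.columns):
        if col == "const":
            continue
        if np.std(A[:, j]) == 0.0:
            raise ValueError(f"rank-deficient design: column {col!r} is constant")
    for j in range(1, A.shape[1]):
        coef, res, *_ = np.linalg.lstsq(A[:, :j], A[:, j], rcond=None)
        fitted = A[:, :j] @ coef
        if np.allclose(fitted, A[:, j], atol=1e-8):
            raise ValueError(
                f"rank-deficient design: column {X.columns[j]!r} is collinear"
            )
    raise ValueError("rank-deficient design")


def _align(*objs):
    idx = objs[0].index
    for o in objs[1:]:
        idx = idx.intersection(o.index)
    return [o.loc[idx] for o in objs]


def fit_linear(
    phenotype: pd.Series,
    score: pd.Series,
    covariates: pd.DataFrame,
    score_id: str = "score",
    phenotype_name: str = "phenotype",
    measure: str = "",
) -> AssociationResult:
    """OLS of a phenotype on a score plus the full covariate set.

    Reports the score coefficient, its SE, t and two-sided p, plus the
    incremental R-squared of the score over the covariate-only model, in
    percent (floored at zero against floating-point noise).
    """
    phenotype, score, covariates = _align(phenotype, score, covariates)
    C = covariate_design(covariates)
    X = pd.concat([pd.Series(1.0, index=score.index, name="const"),
                   score.rename("score"), C], axis=1)
    _check_full_rank(X)
    y = phenotype.astype(float)
    full = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, X.drop(columns="score")).fit()
    r2_inc = max(full.rsquared - reduced.rsquared, 0.0) * 100.0
    return AssociationResult(
        score_id=score_id,
        phenotype=phenotype_name,
        measure=measure,
        model="linear",
        effect=float(full.params["score"]),
        se=float(full.bse["score"]),
        t=float(full.tvalues["score"]),
        p=float(max(full.pvalues["score"], _TINY_P)),
        r2_increment_pct=float(r2_inc),
        n_subjects=int(len(y)),
    )


def fit_bilateral_mixed(
    long_table: pd.DataFrame,
    score: pd.Series,
    covariates: pd.DataFrame | None = None,
    score_id: str = "score",
    phenotype_name: str = "phenotype",
    measure: str = "",
    maxiter: int = 200,
) -> AssociationResult:
    """Random-intercept mixed model for one bilateral tract.

    ``long_table`` has two rows per subject (columns ``subject_id``,
    ``hemisphere``, ``value`` and optionally the covariates; otherwise pass
    ``covariates`` indexed by subject id). Fixed effects are the score, a
    right-hemisphere indicator and the covariate set; a per-subject random
    intercept absorbs the within-subject correlation. Estimation is REML.
    A non-converged fit is returned flagged (``converged=False``) and later
    excluded from FDR with a warning.
    """
    df = long_table.copy()
    df["score"] = df["subject_id"].map(score)
    if covariates is not None:
        df = df.join(covariates, on="subject_id", validate="many_to_one")
    df = df.dropna(subset=["value", "score"])
    hemi = (df["hemisphere"] == "right").astype(float).rename("hemi_right")
    cov_cols = [c for c in df.columns
                if c in set(NUMERIC_COVARIATES) | set(CATEGORICAL_COVARIATES)]
    C = covariate_design(df[cov_cols]) if cov_cols else pd.DataFrame(index=df.index)
    X = pd.concat(
        [pd.Series(1.0, index=df.index, name="const"),
         df["score"].astype(float), hemi, C],
        axis=1,
    )
    _check_full_rank(X)
    model = sm.MixedLM(df["value"].astype(float), X, groups=df["subject_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, maxiter=maxiter, method="lbfgs")
    converged = bool(getattr(fit, "converged", True))
    if not converged:
        logger.warning("mixed model %s / %s (%s) did not converge",
                       score_id, phenotype_name, measure)
    return AssociationResult(
        score_id=score_id,
        phenotype=phenotype_name,
        measure=measure,
        model="mixed_bilateral",
        effect=float(fit.params["score"]),
        se=float(fit.bse["score"]),
        t=float(fit.tvalues["score"]),
        p=float(max(fit.pvalues["score"], _TINY_P)),
        n_subjects=int(df["subject_id"].nunique()),
        converged=converged,
    )


def fit_quadratic(
    phenotype: pd.Series,
    score: pd.Series,
    covariates: pd.DataFrame,
    score_id: str = "score",
    phenotype_name: str = "phenotype",
    measure: str = "",
) -> QuadraticResult:
    """Extra variance explained by the squared score, beyond the linear model.

    The score is z-standardized, squared, and the square centered before entry.
    """
    phenotype, score, covariates = _align(phenotype, score, covariates)
    sd = score.std(ddof=0)
    if sd == 0.0:
        raise ValueError("rank-deficient design: column 'score' is constant")
    z = (score - score.mean()) / sd
    z2 = z ** 2
    z2 = z2 - z2.mean()
    C = covariate_design(covariates)
    const = pd.Series(1.0, index=score.index, name="const")
    X_lin = pd.concat([const, z.rename("score"), C], axis=1)
    X_quad = pd.concat([const, z.rename("score"), z2.rename("score_sq"), C], axis=1)
    _check_full_rank(X_quad)
    y = phenotype.astype(float)
    lin = sm.OLS(y, X_lin).fit()
    quad = sm.OLS(y, X_quad).fit()
    return QuadraticResult(
        score_id=score_id,
        phenotype=phenotype_name,
        measure=measure,
        r2_quadratic_pct=float(max(quad.rsquared - lin.rsquared, 0.0) * 100.0),
        p_quadratic=float(max(quad.pvalues["score_sq"], _TINY_P)),
    )


def linear_scan(
    phenotypes: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    measure: str = "",
    model_label: str = "linear",
) -> list[AssociationResult]:
    """Every (score, phenotype) OLS fit of a family at once.

    Equivalent to calling :func:`fit_linear` for each pair (tested to 1e-10):
    by Frisch-Waugh, residualizing both sides on the covariates (plus
    intercept) leaves the score coefficient, its SE and t unchanged, with the
    degrees of freedom of the full model.
    """
    phenotypes, scores, covariates = _align(phenotypes, scores, covariates)
    C = covariate_design(covariates)
    X0 = np.column_stack([np.ones(len(C)), C.to_numpy(dtype=float)])
    _check_full_rank(pd.DataFrame(X0, columns=["const", *C.columns]))
    Y = phenotypes.to_numpy(dtype=float)
    S = scores.to_numpy(dtype=float)
    Q, _ = np.linalg.qr(X0)
    Yr = Y - Q @ (Q.T @ Y)
    Sr = S - Q @ (Q.T @ S)
    n, p0 = X0.shape
    dof = n - p0 - 1
    ss_s = np.einsum("ij,ij->j", Sr, Sr)  # per-score residual sum of squares
    ss_raw = np.einsum("ij,ij->j", S - S.mean(axis=0), S - S.mean(axis=0))
    degenerate = ss_s <= 1e-10 * np.maximum(ss_raw, 1e-300)
    if np.any(degenerate):
        bad = list(scores.columns[degenerate])
        raise ValueError(f"rank-deficient design: score column(s) {bad} collinear with covariates")
    ss_y = np.einsum("ij,ij->j", Yr, Yr)
    cross = Sr.T @ Yr  # scores x phenotypes
    beta = cross / ss_s[:, None]
    rss = np.maximum(ss_y[None, :] - beta * cross, 0.0)
    se = np.sqrt(rss / dof / ss_s[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf)
    from scipy import stats as sps
    pval = np.maximum(2.0 * sps.t.sf(np.abs(tval), dof), _TINY_P)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    r2_cov = 1.0 - ss_y / tss
    r2_full = 1.0 - rss / tss[None, :]
    r2_inc = np.maximum(r2_full - r2_cov[None, :], 0.0) * 100.0
    out = []
    for i, sid in enumerate(scores.columns):
        for j, ph in enumerate(phenotypes.columns):
            out.append(
                AssociationResult(
                    score_id=str(sid), phenotype=str(ph), measure=measure,
                    model=model_label,
                    effect=float(beta[i, j]), se=float(se[i, j]),
                    t=float(tval[i, j]), p=float(pval[i, j]),
                    r2_increment_pct=float(r2_inc[i, j]), n_subjects=int(n),
                )
            )
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (R's ``p.adjust`` "fdr")."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fdr_correct(
    results: list[AssociationResult], family_label: str = ""
) -> list[AssociationResult]:
    """BH adjustment within one test family; non-converged fits are excluded.

    Returns new result records with ``q`` filled in, in the input order (minus
    any excluded non-converged fits, which are logged).
    """
    usable = [r for r in results if r.converged]
    dropped = len(results) - len(usable)
    if dropped:
        logger.warning("family %s: excluded %d non-converged fit(s) from FDR",
                       family_label or "<unnamed>", dropped)
    if not usable:
        return []
    q = bh_adjust(np.array([r.p for r in usable]))
    logger.info("family %s: %d tests, %d significant at q<0.05",
                family_label or "<unnamed>", len(usable), int((q < 0.05).sum()))
    return [dataclasses.replace(r, q=float(qi)) for r, qi in zip(usable, q)]


def overlap_comparison(
    gene: str,
    scores_by_study: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    measure: str = "",
) -> list[AssociationResult]:
    """Side-by-side fits of a gene scored from both discovery studies.

    ``scores_by_study`` holds one column per score (``gene@study``); exactly the
    two columns for ``gene`` are used, bypassing de-duplication. Each study's
    score is fitted against every phenotype; paired results come back ordered
    phenotype-major so the two studies sit next to each other.
    """
    cols = [c for c in scores_by_study.columns if c.split("@")[0] == gene]
    if len(cols) < 2:
        raise KeyError(f"gene {gene!r} is not scored in both studies")
    res = linear_scan(phenotypes, scores_by_study[cols], covariates, measure=measure)
    res.sort(key=lambda r: (r.phenotype, r.score_id))
    return res


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Results as a table mirroring the published column layout."""
    return pd.DataFrame(
        {
            "score": [r.score_id for r in results],
            "phenotype": [r.phenotype for r in results],
            "measure": [r.measure for r in results],
            "model": [r.model for r in results],
            "effect": [r.effect for r in results],
            "se": [r.se for r in results],
            "t": [r.t for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "r2_pct": [r.r2_increment_pct for r in results],
            "n": [r.n_subjects for r in results],
        }
    )
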