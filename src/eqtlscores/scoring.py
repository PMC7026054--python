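"""eQTL score construction from summary statistics and cohort dosages.

A gene's eQTL score for individual *i* is ``score(i) = g_i @ (R^+ @ beta)`` where
``g_i`` are the individual's dosages (0/1/2 copies of the cohort reference allele)
over the gene's selected SNPs, ``beta`` the per-SNP eQTL effect sizes harmonized to
those reference alleles, and ``R^+`` the generalized inverse of the SNP correlation
matrix estimated from a reference panel. SNPs enter a score if their discovery
p-value passes the threshold (default 1e-5, inclusive). When the same gene is scored
in both discovery studies, only the study whose score contains the SNP with the
smallest p-value is retained.

The :class:`EQTLScorer` transformer packages the whole construction: ``fit`` takes
summary statistics plus the LD reference panel and builds score definitions;
``transform`` maps cohort genotypes to the subjects x scores matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import ld as ld_module
from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_P_THRESHOLD",
    "ScoreDefinition",
    "ScoreMatrix",
    "select_snps",
    "harmonize_alleles",
    "build_score_definitions",
    "compute_scores",
    "deduplicate_scores",
    "EQTLScorer",
]

#: discovery p-value threshold for a SNP to enter a score (inclusive)
DEFAULT_P_THRESHOLD = 1e-5

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class ScoreDefinition:
    """A gene's score: ordered SNPs, harmonized betas and LD-adjusted weights."""

    gene: str
    study: str
    snp_ids: tuple[str, ...]
    harmonized_betas: np.ndarray
    weights: np.ndarray
    best_p: float

    def __post_init__(self) -> None:
        if not (len(self.snp_ids) == len(self.weights) == len(self.harmonized_betas) >= 1):
            raise ValueError("snp_ids, betas and weights must be equal-length, non-empty")

    @property
    def score_id(self) -> str:
        return f"{self.gene}@{self.study}"

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class ScoreMatrix:
    """Subjects x scores matrix with one column per retained score definition."""

    subject_ids: tuple[str, ...]
    definitions: tuple[ScoreDefinition, ...]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.subject_ids), len(self.definitions)):
            raise ValueError("score matrix shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("score matrix contains missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=[d.score_id for d in self.definitions],
        )

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [d.gene for d in self.definitions],
                "study": [d.study for d in self.definitions],
                "n_snps": [d.n_snps for d in self.definitions],
                "best_p": [d.best_p for d in self.definitions],
                "snps": [",".join(d.snp_ids) for d in self.definitions],
            }
        )


def select_snps(records: pd.DataFrame, p_threshold: float = DEFAULT_P_THRESHOLD) -> pd.DataFrame:
    """Keep records with discovery p <= threshold (inclusive boundary).

    Genes whose SNPs all fail the threshold drop out entirely, simply by having
    no surviving rows.
    """
    if len(records) == 0:
        return records.copy()
    return records.loc[records["p"] <= p_threshold].copy()


def harmonize_alleles(records: pd.DataFrame, cohort_allele_map: pd.DataFrame) -> pd.DataFrame:
    """Align summary-statistic effect alleles to the cohort's counted alleles.

    ``cohort_allele_map`` is indexed by SNP id with columns ``ref_allele`` (the
    allele the dosage counts) and ``other_allele``. Where a record's effect allele
    already is the cohort reference allele, beta is unchanged; where it is the
    other allele, beta is sign-flipped and the alleles swapped. Strand-ambiguous
    SNPs (A/T, C/G), SNPs absent from the cohort, and irreconcilable allele pairs
    are dropped with a logged warning.
    """
    kept = []
    n_ambiguous = n_missing = n_mismatch = 0
    for rec in records.itertuples(index=False):
        pair = frozenset((rec.effect_allele, rec.other_allele))
        if pair in _AMBIGUOUS:
            n_ambiguous += 1
            continue
        if rec.snp not in cohort_allele_map.index:
            n_missing += 1
            continue
        ref = cohort_allele_map.loc[rec.snp, "ref_allele"]
        other = cohort_allele_map.loc[rec.snp, "other_allele"]
        rec = rec._asdict()
        if rec["effect_allele"] == ref and rec["other_allele"] == other:
            kept.append(rec)
        elif rec["effect_allele"] == other and rec["other_allele"] == ref:
            rec["beta"] = -rec["beta"]
            rec["effect_allele"], rec["other_allele"] = ref, other
            kept.append(rec)
        else:
            n_mismatch += 1
    if n_ambiguous:
        logger.warning("harmonization dropped %d strand-ambiguous SNP record(s)", n_ambiguous)
    if n_missing:
        logger.warning("harmonization dropped %d record(s) absent from the cohort", n_missing)
    if n_mismatch:
        logger.warning("harmonization dropped %d record(s) with irreconcilable alleles", n_mismatch)
    return pd.DataFrame(kept, columns=records.columns)


def build_score_definitions(
    records: pd.DataFrame,
    panel: GenotypeMatrix,
    tol: float = ld_module.DEFAULT_TOL,
) -> list[ScoreDefinition]:
    """LD-adjusted score definitions, one per (gene, study) group.

    SNPs are ordered deterministically by genomic position then id; the gene's
    correlation matrix R is estimated from the reference panel over exactly those
    SNPs, and the weights are ``pinv(R) @ beta``.
    """
    defs: list[ScoreDefinition] = []
    for (gene, study), grp in records.groupby(["gene", "study"], sort=True):
        grp = grp.sort_values(["pos", "snp"], kind="mergesort")
        if len(grp) == 0:
            logger.warning("gene %s (%s): no SNPs after harmonization; skipped", gene, study)
            continue
        snp_ids = tuple(grp["snp"])
        beta = grp["beta"].to_numpy(dtype=float)
        R = ld_module.compute_ld_matrix(panel, snp_ids)
        Rinv = ld_module.generalized_inverse(R, tol=tol)
        weights = Rinv.Rinv @ beta
        defs.append(
            ScoreDefinition(
                gene=gene,
                study=study,
                snp_ids=snp_ids,
                harmonized_betas=beta,
                weights=weights,
                best_p=float(grp["p"].min()),
            )
        )
    return defs


def compute_scores(
    defs: list[ScoreDefinition],
    cohort: GenotypeMatrix,
    standardize: bool = True,
) -> ScoreMatrix:
    """Per-subject scores: the matrix product of cohort dosages with each weight vector.

    With ``standardize=True`` (the default, matching how the scores enter the
    association models) each column is z-scored across subjects; a zero-variance
    column is left centered at zero.
    """
    n = len(cohort.subject_ids)
    values = np.empty((n, len(defs)), dtype=float)
    for k, d in enumerate(defs):
        try:
            cols = [cohort.snp_index(s) for s in d.snp_ids]
        except KeyError as e:
            raise KeyError(
                f"SNP {e.args[0]!r} of gene {d.gene} ({d.study}) missing from cohort genotypes"
            ) from None
        values[:, k] = cohort.dosages[:, cols].astype(float) @ d.weights
    if standardize and n > 0:
        mean = values.mean(axis=0)
        sd = values.std(axis=0)
        values = (values - mean) / np.where(sd == 0, 1.0, sd)
    return ScoreMatrix(
        subject_ids=tuple(cohort.subject_ids),
        definitions=tuple(defs),
        values=values,
        standardized=standardize,
    )


def deduplicate_scores(
    defs_study_a: list[ScoreDefinition],
    defs_study_b: list[ScoreDefinition],
) -> list[ScoreDefinition]:
    """Resolve genes scored in both studies: keep the score with the smallest SNP p-value.

    Genes present in only one study are kept unconditionally. An exact tie on the
    best p-value is broken in favour of the first-listed study, so the outcome is
    deterministic. The result is sorted by gene id.
    """
    by_gene_a = {d.gene: d for d in defs_study_a}
    by_gene_b = {d.gene: d for d in defs_study_b}
    retained: list[ScoreDefinition] = []
    for gene in sorted(set(by_gene_a) | set(by_gene_b)):
        a, b = by_gene_a.get(gene), by_gene_b.get(gene)
        if a is not None and b is not None:
            retained.append(a if a.best_p <= b.best_p else b)
        else:
            retained.append(a if a is not None else b)
    return retained


class EQTLScorer(TransformerMixin, BaseEstimator):
    """Transformer from cohort genotypes to LD-adjusted eQTL scores.

    Parameters
    ----------
    p_threshold : float
        Inclusive discovery p-value threshold for SNP selection.
    tol : float
        Relative singular-value cutoff of the generalized inverse of R.
    standardize : bool
        Whether ``transform`` z-scores each score column across subjects.
    deduplicate : bool
        Whether genes scored by both studies are resolved to the study with the
        smallest SNP p-value (set False for side-by-side overlap comparisons).

    Attributes
    ----------
    definitions_ : list of ScoreDefinition
        Retained score definitions after thresholding, harmonization, LD
        adjustment and (optionally) cross-study de-duplication.
    n_built_per_study_ : dict
        Scores built per study before de-duplication.
    """

    def __init__(
        self,
        p_threshold: float = DEFAULT_P_THRESHOLD,
        tol: float = ld_module.DEFAULT_TOL,
        standardize: bool = True,
        deduplicate: bool = True,
    ):
        self.p_threshold = p_threshold
        self.tol = tol
        self.standardize = standardize
        self.deduplicate = deduplicate

    def fit(self, sumstats, panel: GenotypeMatrix, cohort_allele_map: pd.DataFrame | None = None):
        """Build score definitions.

        Parameters
        ----------
        sumstats : DataFrame or sequence of DataFrames
            Summary statistics of one or more discovery studies (concatenated
            tables are also accepted; studies are told apart by the ``study``
            column, in first-appearance order for tie-breaking).
        panel : GenotypeMatrix
            LD reference panel; its allele coding defines the counted alleles
            unless ``cohort_allele_map`` is given.
        """
        if isinstance(sumstats, (list, tuple)):
            records = pd.concat(sumstats, ignore_index=True)
        else:
            records = sumstats.copy()
        if cohort_allele_map is None:
            cohort_allele_map = panel.allele_map()
        study_order = list(dict.fromkeys(records["study"]))
        selected = select_snps(records, self.p_threshold)
        harmonized = harmonize_alleles(selected, cohort_allele_map)
        self.n_records_ = int(len(records))
        self.n_after_threshold_ = int(len(selected))
        self.n_after_harmonization_ = int(len(harmonized))
        per_study = [
            build_score_definitions(
                harmonized.loc[harmonized["study"] == s], panel, tol=self.tol
            )
            for s in study_order
        ]
        self.study_order_ = study_order
        self.n_built_per_study_ = {s: len(d) for s, d in zip(study_order, per_study)}
        if self.deduplicate and len(per_study) == 2:
            self.definitions_ = deduplicate_scores(per_study[0], per_study[1])
        else:
            self.definitions_ = [d for defs in per_study for d in defs]
        return self

    def transform(self, cohort: GenotypeMatrix) -> pd.DataFrame:
        """Subjects x scores DataFrame for a genotyped cohort."""
        if not hasattr(self, "definitions_"):
            raise RuntimeError("EQTLScorer must be fitted before transform")
        return compute_scores(
            self.definitions_, cohort, standardize=self.standardize
        ).to_frame()

    def score_matrix(self, cohort: GenotypeMatrix) -> ScoreMatrix:
        """Like :meth:`transform` but returns the richer ScoreMatrix container."""
        if not hasattr(self, "definitions_"):
            raise RuntimeError("EQTLScorer must be fitted before transform")
        return compute_scores(self.definitions_, cohort, standardize=self.standardize)
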