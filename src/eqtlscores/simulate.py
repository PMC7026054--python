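"""Synthetic data generation with known ground truth.

Generates every input the pipeline needs, emulating the structure of the real study
inputs without any download:

* a reference panel and a target cohort of genotype dosages with block-wise LD
  (correlated latent Gaussians thresholded at allele-frequency quantiles, two
  haplotypes summed);
* two eQTL discovery studies with partially overlapping gene sets, each gene's
  per-SNP marginal effect sizes and p-values estimated by regression of a simulated
  expression trait on panel dosages;
* realistic subject covariates (age, sex, genetic PCs, scanner site, genotype
  array, head-position coordinates, a relatedness/overlap exclusion flag);
* bilateral FA/MD tract phenotypes with a shared global factor, category factors,
  tract-specific structure, hemispheric noise, small covariate effects, and a
  planted standardized effect of each causal gene's TRUE expression score
  (negative on FA, positive on MD by default).

All outputs are bit-reproducible given the same configuration and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import MEASURES, TractAtlas

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "GroundTruth",
    "make_snp_table",
    "simulate_reference_panel",
    "simulate_cohort",
    "simulate_eqtl_summaries",
    "simulate_tract_phenotypes",
]

#: column order of a summary-statistics table
SUMSTAT_COLUMNS = (
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "beta", "se", "p", "gene", "study",
)

# unambiguous allele pairs (strand flips are resolvable); A/T and C/G are ambiguous
_UNAMBIGUOUS_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))
_AMBIGUOUS_PAIRS = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale study: a 2,000-individual reference panel,
    a 2,000-subject imaging cohort, 20 LD blocks of 25 SNPs with within-block
    latent correlation 0.5, two eQTL studies of 30 genes sharing 10, a planted
    standardized effect of 0.05 (the magnitude of the reported associations),
    and left-right tract correlation 0.75.
    """

    n_ref: int = 2000
    n_subjects: int = 2000
    n_blocks: int = 20
    snps_per_block: int = 25
    rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes_study_a: int = 30
    n_genes_study_b: int = 30
    n_overlap_genes: int = 10
    snps_per_gene: tuple[int, int] = (1, 15)
    n_causal_genes: int = 2
    effect_size: float = 0.05
    hemi_corr: float = 0.75
    covariate_effect: float = 0.03
    exclusion_fraction: float = 0.02
    ambiguous_snp_fraction: float = 0.0
    lead_snp_h2: float = 0.04
    background_h2: float = 0.02
    study_a: str = "study_a"
    study_b: str = "study_b"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ref", "n_subjects", "n_blocks", "snps_per_block"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if min(self.n_genes_study_a, self.n_genes_study_b) < self.n_overlap_genes:
            raise ValueError("n_overlap_genes exceeds a study's gene count")
        if self.n_overlap_genes < 0:
            raise ValueError("n_overlap_genes must be non-negative")
        if not 0.0 <= self.hemi_corr <= 1.0:
            raise ValueError("hemi_corr must lie in [0, 1]")
        lo, hi = self.snps_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("snps_per_gene bounds must satisfy 1 <= low <= high")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


class GenotypeMatrix:
    """Subjects x SNPs dosage matrix coded 0/1/2 copies of the reference allele."""

    def __init__(self, subject_ids, snps: pd.DataFrame, dosages: np.ndarray):
        self.subject_ids = list(subject_ids)
        self.snps = snps
        self.dosages = np.asarray(dosages)
        if self.dosages.shape != (len(self.subject_ids), len(snps)):
            raise ValueError("dosage matrix shape does not match ids")
        self._index = {s: j for j, s in enumerate(snps.index)}

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    def snp_index(self, snp_id: str) -> int:
        return self._index[snp_id]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def allele_map(self) -> pd.DataFrame:
        """Per-SNP (reference, other) alleles: the dosage counts the reference allele."""
        return self.snps[["ref_allele", "other_allele"]]


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for parameter-recovery tests.

    ``true_effects[gene]`` maps each of the gene's SNPs to its true effect on the
    (standardized-dosage scale) synthetic expression trait. ``planted`` lists
    (gene, measure, standardized effect) triples; the effect is applied through the
    subject's true expression score to every tract variable of that measure.
    """

    true_effects: dict[str, dict[str, float]]
    planted: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)

    @property
    def causal_genes(self) -> list[str]:
        seen: list[str] = []
        for g, _, _ in self.planted:
            if g not in seen:
                seen.append(g)
        return seen

    def true_expression_score(self, genotypes: GenotypeMatrix, gene: str) -> np.ndarray:
        """The gene's true expression score in a cohort, z-standardized."""
        eff = self.true_effects[gene]
        cols = [genotypes.snp_index(s) for s in eff]
        G = genotypes.dosages[:, cols].astype(float)
        Z = (G - G.mean(axis=0)) / np.where(G.std(axis=0) == 0, 1.0, G.std(axis=0))
        s = Z @ np.array(list(eff.values()))
        sd = s.std()
        return (s - s.mean()) / (sd if sd > 0 else 1.0)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams keyed off the one seed
    return np.random.default_rng([stream, cfg.seed])


def make_snp_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Deterministic SNP metadata shared by the reference panel and the cohort.

    One row per SNP: chromosome, position, LD block, reference/other alleles and
    the reference-allele frequency (the reference allele is the minor allele, with
    frequency drawn uniformly from ``maf_range``).
    """
    rng = _rng(cfg, 1)
    rows = []
    for b in range(cfg.n_blocks):
        chrom = (b % 22) + 1
        for j in range(cfg.snps_per_block):
            if rng.uniform() < cfg.ambiguous_snp_fraction:
                pair = _AMBIGUOUS_PAIRS[rng.integers(len(_AMBIGUOUS_PAIRS))]
            else:
                pair = _UNAMBIGUOUS_PAIRS[rng.integers(len(_UNAMBIGUOUS_PAIRS))]
            rows.append(
                {
                    "snp": f"rs{b:03d}{j:03d}",
                    "chr": chrom,
                    "pos": 1_000_000 * (b + 1) + 5_000 * j,
                    "block": b,
                    "ref_allele": pair[0],
                    "other_allele": pair[1],
                    "maf": rng.uniform(*cfg.maf_range),
                }
            )
    return pd.DataFrame(rows).set_index("snp")


def _draw_dosages(snps: pd.DataFrame, n: int, rho: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Two correlated latent haplotypes per block, thresholded at the MAF quantile."""
    m = len(snps)
    dosages = np.zeros((n, m), dtype=np.int8)
    thresholds = stats.norm.ppf(snps["maf"].to_numpy())
    blocks = snps["block"].to_numpy()
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        for _hap in range(2):
            u = rng.standard_normal(n)
            eps = rng.standard_normal((n, cols.size))
            z = np.sqrt(rho) * u[:, None] + np.sqrt(1.0 - rho) * eps
            dosages[:, cols] += (z < thresholds[cols]).astype(np.int8)
    return dosages


def simulate_reference_panel(cfg: SimulationConfig) -> GenotypeMatrix:
    """LD-reference genotype panel: ``n_ref`` individuals x all SNPs."""
    snps = make_snp_table(cfg)
    dosages = _draw_dosages(snps, cfg.n_ref, cfg.rho, _rng(cfg, 2))
    ids = [f"ref{i:05d}" for i in range(cfg.n_ref)]
    return GenotypeMatrix(ids, snps, dosages)


def simulate_cohort(panel_spec, cfg: SimulationConfig):
    """Target-cohort dosages plus a covariate table.

    ``panel_spec`` is a SNP metadata table (or a GenotypeMatrix whose table is
    reused) so cohort and panel share SNP identities, alleles and frequencies.
    Covariates: age (uniform over the study's 45.92-80.67 range), sex, fifteen
    genetic principal components, scanner site, genotype array, three head-position
    coordinates, and a relatedness/cohort-overlap exclusion flag set on a random
    ``exclusion_fraction`` of subjects.
    """
    snps = panel_spec.snps if isinstance(panel_spec, GenotypeMatrix) else panel_spec
    dosages = _draw_dosages(snps, cfg.n_subjects, cfg.rho, _rng(cfg, 3))
    ids = [f"S{i:06d}" for i in range(cfg.n_subjects)]
    genotypes = GenotypeMatrix(ids, snps, dosages)

    rng = _rng(cfg, 4)
    n = cfg.n_subjects
    age = rng.uniform(45.92, 80.67, size=n)
    cov = pd.DataFrame(index=pd.Index(ids, name="subject_id"))
    cov["age"] = age
    cov["age_squared"] = age ** 2
    cov["sex"] = rng.integers(0, 2, size=n)
    for k in range(1, 16):
        cov[f"pc{k}"] = rng.standard_normal(n)
    cov["pos_x"] = rng.standard_normal(n)
    cov["pos_y"] = rng.standard_normal(n)
    cov["pos_z"] = rng.standard_normal(n)
    cov["site"] = rng.choice([1, 2], size=n, p=[0.85, 0.15])
    cov["array"] = rng.choice([1, 2], size=n, p=[0.1, 0.9])
    cov["excluded"] = rng.uniform(size=n) < cfg.exclusion_fraction
    return genotypes, cov


def _marginal_stats(g: np.ndarray, y: np.ndarray):
    """Simple-regression slope, SE and two-sided p of y on one dosage column."""
    n = len(y)
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    sxy = float(gc @ yc)
    syy = float(yc @ yc)
    if sxx == 0.0:  # monomorphic in this finite panel draw
        return 0.0, np.inf, 1.0
    beta = sxy / sxx
    rss = max(syy - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0:
        return beta, se, np.finfo(float).tiny
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return beta, se, max(p, np.finfo(float).tiny)


def simulate_eqtl_summaries(panel: GenotypeMatrix, cfg: SimulationConfig):
    """Two eQTL discovery studies plus the ground truth behind them.

    Every gene is assigned 1-15 SNPs (configurable) within a single LD block; a
    synthetic expression trait is built from true SNP effects (one lead SNP with
    variance share ``lead_snp_h2`` plus polygenic background) and Gaussian noise,
    and each SNP's marginal effect size and p-value are estimated by regression
    on panel dosages. Exactly ``n_overlap_genes`` genes appear in both studies,
    with statistics estimated from independent expression noise realisations.

    Returns (sumstats_study_a, sumstats_study_b, GroundTruth) where the summary
    tables have columns ``SUMSTAT_COLUMNS``.
    """
    rng = _rng(cfg, 5)
    n_unique = cfg.n_genes_study_a + cfg.n_genes_study_b - cfg.n_overlap_genes
    genes = [f"GENE{i:04d}" for i in range(n_unique)]
    # first n_overlap genes are shared; remaining split between the studies
    shared = genes[: cfg.n_overlap_genes]
    only_a = genes[cfg.n_overlap_genes: cfg.n_genes_study_a]
    only_b = genes[cfg.n_genes_study_a:]
    study_genes = {cfg.study_a: shared + only_a, cfg.study_b: shared + only_b}

    blocks = panel.snps["block"].to_numpy()
    true_effects: dict[str, dict[str, float]] = {}
    snp_max = min(cfg.snps_per_gene[1], cfg.snps_per_block)
    for i, gene in enumerate(genes):
        b = i % cfg.n_blocks
        cols = np.flatnonzero(blocks == b)
        k = int(rng.integers(cfg.snps_per_gene[0], snp_max + 1))
        chosen = np.sort(rng.choice(cols, size=k, replace=False))
        snp_ids = [panel.snps.index[j] for j in chosen]
        effects = rng.normal(0.0, np.sqrt(cfg.background_h2 / k), size=k)
        effects[rng.integers(k)] += np.sqrt(cfg.lead_snp_h2) * rng.choice([-1.0, 1.0])
        true_effects[gene] = dict(zip(snp_ids, effects))

    tables = {}
    for study, gene_list in study_genes.items():
        rows = []
        for gene in gene_list:
            eff = true_effects[gene]
            cols = [panel.snp_index(s) for s in eff]
            G = panel.dosages[:, cols].astype(float)
            sd = G.std(axis=0)
            Z = (G - G.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
            u = np.array(list(eff.values()))
            genetic = Z @ u
            noise_sd = np.sqrt(max(1.0 - float(genetic.var()), 0.1))
            y = genetic + rng.normal(0.0, noise_sd, size=cfg.n_ref)
            for s, j in zip(eff, cols):
                beta, se, p = _marginal_stats(panel.dosages[:, j].astype(float), y)
                meta = panel.snps.loc[s]
                if rng.uniform() < 0.3:  # report the non-reference allele as effect allele
                    ea, oa, beta = meta["other_allele"], meta["ref_allele"], -beta
                else:
                    ea, oa = meta["ref_allele"], meta["other_allele"]
                rows.append({
                    "snp": s, "chr": meta["chr"], "pos": meta["pos"],
                    "effect_allele": ea, "other_allele": oa,
                    "beta": beta, "se": se, "p": p, "gene": gene, "study": study,
                })
        tables[study] = pd.DataFrame(rows, columns=list(SUMSTAT_COLUMNS))

    causal = genes[: cfg.n_causal_genes] if cfg.effect_size != 0.0 else []
    planted = tuple(
        (g, m, -cfg.effect_size if m == "FA" else cfg.effect_size)
        for g in causal for m in MEASURES
    )
    truth = GroundTruth(true_effects=true_effects, planted=planted)
    return tables[cfg.study_a], tables[cfg.study_b], truth


# variance shares of the subject-level (hemisphere-shared) phenotype component
_GLOBAL_SHARE = 0.45
_CATEGORY_SHARE = 0.20
_TRACT_SHARE = 0.35


def simulate_tract_phenotypes(
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    atlas: TractAtlas,
    cfg: SimulationConfig,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """FA/MD values for every tract variable, long format.

    Each value is a sum of a global latent factor, a category factor, a
    tract-specific subject factor (all shared between hemispheres, with total
    variance ``hemi_corr``), hemisphere-specific noise (variance 1 - hemi_corr),
    small covariate effects, and the planted genetic effect acting through the
    causal genes' true expression scores (negative on FA, positive on MD).
    The left-right correlation of a bilateral tract is hemi_corr up to the small
    covariate and genetic contributions.
    """
    rng = _rng(cfg, 6)
    n = len(genotypes.subject_ids)
    subject_ids = genotypes.subject_ids

    cov_term = {m: np.zeros(n) for m in MEASURES}
    if covariates is not None:
        c = cfg.covariate_effect
        age_z = (covariates["age"] - covariates["age"].mean()) / covariates["age"].std()
        base = (
            age_z.to_numpy()
            + 0.5 * (covariates["sex"].to_numpy() - 0.5)
            + 0.5 * (covariates["site"].to_numpy() - 1)
            + 0.25 * covariates["pos_x"].to_numpy()
        )
        cov_term["FA"] = -c * base  # older age etc. lower FA ...
        cov_term["MD"] = c * base   # ... and raise MD

    genetic_term = {m: np.zeros(n) for m in MEASURES}
    for gene, measure, effect in truth.planted:
        genetic_term[measure] = genetic_term[measure] + effect * truth.true_expression_score(
            genotypes, gene
        )

    sd_global = np.sqrt(cfg.hemi_corr * _GLOBAL_SHARE)
    sd_cat = np.sqrt(cfg.hemi_corr * _CATEGORY_SHARE)
    sd_tract = np.sqrt(cfg.hemi_corr * _TRACT_SHARE)
    sd_hemi = np.sqrt(1.0 - cfg.hemi_corr)

    records = []
    for measure in MEASURES:
        f_global = rng.standard_normal(n)
        f_cat = {c: rng.standard_normal(n) for c in ("association", "thalamic", "projection")}
        for tract in atlas.tracts:
            f_tract = rng.standard_normal(n)
            shared = (
                sd_global * f_global
                + sd_cat * f_cat[tract.category]
                + sd_tract * f_tract
                + cov_term[measure]
                + genetic_term[measure]
            )
            for _, hemi in tract.variables():
                value = shared + sd_hemi * rng.standard_normal(n)
                records.append(
                    pd.DataFrame({
                        "subject_id": subject_ids,
                        "measure": measure,
                        "tract_id": tract.tract_id,
                        "hemisphere": hemi,
                        "value": value,
                    })
                )
    return pd.concat(records, ignore_index=True)
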