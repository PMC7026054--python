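# Methods

`eqtlscores` implements a pipeline that links genetic proxies of gene expression to
diffusion-MRI measures of white-matter microstructure, and a synthetic-data generator
that lets every stage be validated against known ground truth.

## The eQTL score model

An eQTL score is a per-individual weighted sum of genotype dosages that acts as a
genetic proxy for the expression of one gene. For individual *i* and gene (trait) *t*,

    score(i, t) = g_i · R⁺ · β_t

where `g_i` is the vector of dosages over the gene's selected SNPs (0/1/2 copies of
the cohort's declared reference allele), `β_t` the vector of per-SNP marginal eQTL
effect sizes from a discovery study, and `R⁺` the Moore–Penrose generalized inverse
of the SNP–SNP Pearson correlation matrix estimated from a reference panel. The
pre-multiplication by `R⁺` decorrelates the marginal effect estimates: for SNPs in
linkage disequilibrium, marginal betas double-count shared signal, and solving
`R w = β` (in the least-squares sense when R is singular) recovers approximate joint
weights. The pseudoinverse rather than a plain inverse is essential because selected
SNPs can be perfectly collinear; for a duplicated SNP pair with equal betas the
pseudoinverse splits the weight evenly (`w = β/2` each), which is the behaviour
tested against the rank-1 closed form.

Construction proceeds in four steps, each an exposed function behind the
`EQTLScorer` transformer (`fit` on summary statistics + reference panel,
`transform` on cohort genotypes):

1. **SNP selection.** Records with discovery `p ≤ 1e-5` are retained. The
   threshold is inclusive: "a threshold of 1e-5" is read as the largest admissible
   p-value. Genes with no surviving SNP drop out.
2. **Allele harmonization.** Effect alleles are aligned to the cohort's counted
   (reference) alleles; where the study reported the opposite allele, the beta is
   sign-flipped and the alleles swapped. Strand-ambiguous SNPs (A/T, C/G) are
   dropped, as are SNPs absent from the cohort or with irreconcilable allele pairs —
   all with logged warnings. Genotype storage is never recoded; only betas flip.
3. **LD adjustment.** R is estimated per gene, jointly over exactly that gene's
   SNPs (ordered by position then id, so the construction is order-invariant), and
   inverted by SVD with singular values below `1e-8 ×` the largest treated as zero.
   The relative cutoff is deliberately conservative; the effective rank is recorded.
4. **Cross-study de-duplication.** When both discovery studies score the same
   gene, only the score whose best SNP p-value is smaller is retained; exact ties go
   to the first-listed study and results are sorted by gene, making the outcome
   deterministic. Genes in one study only are kept unconditionally, so
   `retained = A + B − overlap` always holds.

Scores are z-standardized across subjects before association, so reported effects
are in phenotype-SD-per-score-SD units (magnitudes of ~0.03–0.06 at biobank scale).

## Phenotypes and QC

The tract atlas contains 15 probabilistic-tractography tracts — 12 bilateral plus
3 midline structures treated as unilateral (forceps minor, forceps major, middle
cerebellar peduncle) — giving 27 tract variables: 12 association-fibre, 6
thalamic-radiation and 9 projection-fibre variables. Each variable carries FA and
MD measures. Note the categories partition *hemisphere-level* variables; at tract
level there are only 15 (e.g. only three thalamic radiations exist), so the
global/category PCA operates on the 27 hemisphere-level variables directly.

Subject QC has two steps, mirroring the study design:

* flagged subjects (relatedness / discovery-cohort overlap, supplied as an input
  flag) are removed first;
* subjects whose **global** measure lies more than 3 SD from the sample mean are
  removed in a **single** pass (mean and SD computed once, not iterated),
  separately for FA and MD — so the two analysis samples may differ. The global
  measure used is the derived global PC1 latent, an explicit assumption since the
  source protocol does not say whether a pre-existing global summary was used.

Latent phenotypes (global + three categories) are the subject scores of the first
unrotated principal component over the relevant variables, computed on the
correlation (standardized) scale because FA/MD variances are heterogeneous across
tracts. The component sign is fixed by requiring a positive mean loading, making
effect directions reproducible run-to-run; latent scores are z-standardized before
association.

## Association models

Every (score, phenotype) pair is modelled separately with the full covariate set:
age, age², sex, 15 genetic principal components, 3 scanner head-position
coordinates, site and genotype array (categoricals treatment-coded against their
first level).

* **Unilateral tracts and latents:** OLS. The reported quantities are the score
  coefficient, SE, t, two-sided p, and the incremental R² (full minus
  covariate-only, in percent, floored at 0 against floating-point noise). A
  Frisch–Waugh residualization scan computes whole families at once and is tested
  to agree with per-pair OLS to 1e-10.
* **Bilateral tracts:** linear mixed model with a per-subject random intercept and
  hemisphere as a within-subject fixed effect, REML estimation (statsmodels
  MixedLM, L-BFGS, iteration cap 200). With one observation per hemisphere no
  richer random structure is identifiable. A non-converged fit is returned flagged
  and excluded from FDR with a warning. When left ≡ right the score effect
  provably equals single-hemisphere OLS; this degenerate equivalence is tested to
  1e-6.
* **Quadratic extension:** the score is standardized, squared, the square centered,
  and added alongside the linear term; the extra variance explained
  (R²(quad) − R²(linear), percent) and the quadratic term's p-value are reported.
* **FDR:** Benjamini–Hochberg (R's `p.adjust` "fdr" equivalent, via statsmodels)
  applied within each test family separately — individual tracts, and
  global + categories — per measure, with significance at q < 0.05. Family sizes
  are logged in the run manifest. With 6,457 scores and 4 latent phenotypes the
  latent family has 25,828 tests.

## The synthetic-data generator

The generator defines the conditions under which the pipeline is validated; its
defaults are fixed and are not tuned against test outcomes.

* **Genotypes.** SNPs live in independent blocks; within a block, two latent
  Gaussian haplotypes per individual with equicorrelation ρ (default 0.5) are
  thresholded at the allele-frequency quantile and summed, giving 0/1/2 dosages
  with block LD at O(n·m) cost. Reference-allele frequencies are uniform on the
  configured range (default 0.05–0.5; the reference allele is the minor allele).
  Real human LD maps, imputation and allele-frequency spectra are deliberately not
  modelled.
* **eQTL studies.** Each gene receives 1–15 SNPs within one block (the count is a
  parameter, since only the observed 1–15 range is known). A synthetic expression
  trait is one lead SNP (variance share 0.04) plus polygenic background (0.02)
  plus Gaussian noise; per-SNP marginal betas, SEs and p-values are estimated by
  regression on the reference panel (n_ref = 2,000 by default, enough for lead
  SNPs to clear p ≤ 1e-5). Overlap genes appear in both studies with independent
  expression-noise realisations. About 30% of records report the non-reference
  allele as effect allele, exercising harmonization.
* **Cohort.** Dosages from the same block process; covariates: age uniform on the
  study's 45.92–80.67 range, sex, 15 iid standard-normal genetic-PC stand-ins,
  site (85/15), array (10/90), head position, and an exclusion flag on a
  configurable fraction (default 2%).
* **Phenotypes.** Each tract value is a sum of a global factor, a category factor
  and a tract factor (subject-level, shared between hemispheres; variance shares
  0.45/0.20/0.35 of `hemi_corr`), hemisphere noise (variance `1 − hemi_corr`,
  default left–right correlation 0.75), small covariate effects (default scale
  0.03 — enough to make covariate adjustment consequential without dominating),
  and the planted effect: for each causal gene, `effect_size` (default 0.05,
  matching the magnitude of the reported associations) times the subject's TRUE
  expression score, negative on FA and positive on MD — the dominant direction
  pattern in the source data. Covariate and genetic terms are subject-level, so
  the realised left–right correlation slightly exceeds `hemi_corr`; both are
  small, and the correlation is asserted to tolerance 0.08.

What passing tests on this generator do **not** show: robustness to realistic LD
decay, imputation error, missing dosages (explicitly unsupported — an error),
non-Gaussian phenotype tails, scanner batch structure beyond a site indicator, or
tissue mismatch between blood eQTL and brain phenotypes.

## Validation-suite design choices

* **Sizes.** The stochastic suites run at desk scale as their defining conditions:
  null calibration uses 20 replicates of ~200 scores × 5 phenotypes at n = 2,000;
  parameter recovery uses 100 replicates at n = 5,000 with a planted 0.05 effect;
  the ranking suite uses 20 end-to-end runs at n = 5,000 with ~20 scores.
* **Null-calibration uniformity.** The KS uniformity test runs on a
  near-independent slice of the null p-values (one phenotype, one score per LD
  block, per replicate) at α = 0.01, because the full family is strongly
  cross-correlated and a pooled KS test would be anti-conservative regardless of
  calibration. The discovery-proportion check uses the full family.
* **Recovery regressor.** The recovery suite regresses on the generator's *true*
  expression score, isolating the association stage's coverage from eQTL-weight
  estimation noise; the estimated-score path is exercised end-to-end by the
  ranking suite, where planted genes must top the |t| ranking.
* **Bookkeeping.** The published score-derivation counts are reproduced as sums
  (3,801 + 7,083 = 10,884 built; 3,286 + 3,171 = 6,457 retained). The printed
  per-study retained counts are not consistent with strict one-gene-in-both-studies
  overlap semantics (they would imply more overlapping genes than one study
  contains, presumably a probe-to-gene multiplicity effect in the real data), so
  the conservation identity `retained = A + B − overlap` is validated on synthetic
  runs, where it holds exactly. Similarly, the printed individual-tract family
  size is not an integer multiple of the score count; the pipeline logs its own
  family sizes rather than forcing a printed value, and the exactly-reproducible
  family is the latent one (6,457 × 4 = 25,828).

## Numerical conventions and degenerate inputs

* Pseudoinverse cutoff: relative 1e-8 (SVD); zero-variance SNPs in the LD panel
  are an error naming the SNP; missing dosages are an error (v1 supports complete
  data only).
* De-duplication ties: first-listed study wins, then gene id lexicographic.
* Zero-variance score columns are left centered at zero by standardization and are
  rejected (named) by the association stage's rank check; constant or collinear
  covariates raise errors naming the column.
* Zero sample SD in outlier exclusion → no exclusions, with a warning.
* p-values are floored at the smallest positive double so downstream logs of
  −log10 p are finite.
* All randomness flows from one integer seed through independent named
  `numpy` Generator streams; identical config + seed reproduces every output file
  byte-for-byte.

## Known limitations

* The mixed model supports exactly the random-intercept structure the design
  identifies; no random slopes, no >2 repeated measures.
* No genome-wide windowed LD estimation or shrinkage estimators — R is always a
  per-gene block.
* The generator's covariates are mutually independent, unlike real cohorts (age
  and site, for instance, are confounded in multi-site studies).
* FA and MD are generated independently of each other, whereas real measures are
  strongly (negatively) correlated; per-measure analyses are unaffected.
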