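import numpy as np
import pandas as pd
import pytest

from eqtlscores import (
    SimulationConfig,
    make_tract_atlas,
    simulate_cohort,
    simulate_eqtl_summaries,
    simulate_reference_panel,
    simulate_tract_phenotypes,
)
from eqtlscores.simulate import GenotypeMatrix


SMALL_CFG = SimulationConfig(
    n_ref=800,
    n_subjects=400,
    n_blocks=6,
    snps_per_block=18,
    n_genes_study_a=6,
    n_genes_study_b=6,
    n_overlap_genes=2,
    snps_per_gene=(1, 8),
    seed=11,
)


@pytest.fixture(scope="session")
def atlas():
    return make_tract_atlas()


@pytest.fixture(scope="session")
def small_cfg():
    return SMALL_CFG


@pytest.fixture(scope="session")
def panel(small_cfg):
    return simulate_reference_panel(small_cfg)


@pytest.fixture(scope="session")
def summaries(panel, small_cfg):
    return simulate_eqtl_summaries(panel, small_cfg)


@pytest.fixture(scope="session")
def cohort_and_covariates(panel, small_cfg):
    return simulate_cohort(panel, small_cfg)


@pytest.fixture(scope="session")
def phenotypes(cohort_and_covariates, summaries, atlas, small_cfg):
    cohort, cov = cohort_and_covariates
    _, _, truth = summaries
    return simulate_tract_phenotypes(cohort, truth, atlas, small_cfg, cov)


def toy_panel(dosages, snp_ids=None, ref=None, other=None) -> GenotypeMatrix:
    """Hand-built genotype container for oracle tests."""
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    snp_ids = snp_ids or [f"snp{j}" for j in range(m)]
    snps = pd.DataFrame(
        {
            "chr": 1,
            "pos": np.arange(m) * 1000 + 100,
            "block": 0,
            "ref_allele": ref or ["A"] * m,
            "other_allele": other or ["G"] * m,
            "maf": 0.3,
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    return GenotypeMatrix([f"id{i}" for i in range(n)], snps, dosages)
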