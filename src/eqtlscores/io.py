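"""Plain-text (tab-separated) readers and writers for all pipeline artifacts.

Formats
-------
summary stats   one row per SNP record: snp, chr, pos, effect_allele,
                other_allele, beta, se, p, gene, study
genotypes       dosage matrix with a subject_id column and one column per SNP,
                plus a sidecar SNP table (snp, chr, pos, block, ref_allele,
                other_allele, maf) declaring the counted (reference) alleles
phenotypes      long table: subject_id, measure, tract_id, hemisphere, value
covariates      one row per subject, indexed by subject_id
ground truth    JSON: per-gene true SNP effects and the planted effects
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import SUMSTAT_COLUMNS, GenotypeMatrix, GroundTruth

__all__ = [
    "read_ld_matrix", "write_ld_matrix",
    "read_sumstats", "write_sumstats",
    "read_genotypes", "write_genotypes",
    "read_phenotypes", "write_phenotypes",
    "read_covariates", "write_covariates",
    "read_ground_truth", "write_ground_truth",
    "write_table", "read_table",
]


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_ld_matrix(ld, path) -> None:
    """Per-gene LD block as a tab-separated matrix with a SNP-id header (debugging aid)."""
    pd.DataFrame(ld.R, index=list(ld.snp_ids), columns=list(ld.snp_ids)).to_csv(
        path, sep="\t", index_label="snp"
    )


def read_ld_matrix(path):
    from .ld import LDMatrix

    df = pd.read_csv(path, sep="\t", index_col="snp")
    return LDMatrix(tuple(df.columns), df.to_numpy())


def write_sumstats(records: pd.DataFrame, path) -> None:
    records.loc[:, list(SUMSTAT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMSTAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-statistics file {path} lacks columns: {sorted(missing)}")
    return df


def write_genotypes(genotypes: GenotypeMatrix, dosage_path, snp_table_path) -> None:
    df = pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.subject_ids, name="subject_id"),
        columns=genotypes.snp_ids,
    )
    df.to_csv(dosage_path, sep="\t")
    genotypes.snps.to_csv(snp_table_path, sep="\t")


def read_genotypes(dosage_path, snp_table_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col="subject_id")
    snps = pd.read_csv(snp_table_path, sep="\t", index_col="snp")
    if list(df.columns) != list(snps.index):
        raise ValueError("dosage columns and SNP table rows disagree")
    return GenotypeMatrix(list(df.index), snps, df.to_numpy())


def write_phenotypes(table: pd.DataFrame, path) -> None:
    cols = ["subject_id", "measure", "tract_id", "hemisphere", "value"]
    table.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t")


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "true_effects": truth.true_effects,
        "planted": [list(p) for p in truth.planted],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        true_effects={g: dict(e) for g, e in payload["true_effects"].items()},
        planted=tuple((g, m, float(v)) for g, m, v in payload["planted"]),
    )
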