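"""SNP–SNP linkage-disequilibrium matrices and their generalized inverses.

The score weights are obtained by pre-multiplying the per-SNP effect-size vector by
the Moore–Penrose generalized inverse of the SNP correlation matrix R estimated from
a reference panel. R is estimated per gene, jointly over the gene's selected SNPs,
so its dimension always matches the effect vector. The pseudoinverse (rather than a
plain inverse) handles perfectly collinear SNPs gracefully.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["LDMatrix", "LDInverse", "compute_ld_matrix", "generalized_inverse"]

#: relative singular-value cutoff used when inverting R
DEFAULT_TOL = 1e-8


@dataclass(frozen=True)
class LDMatrix:
    """A Pearson correlation matrix over an ordered set of SNPs."""

    snp_ids: tuple[str, ...]
    R: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError("R shape does not match the number of SNP ids")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("R must have unit diagonal")
        if np.any(np.abs(R) > 1.0 + 1e-8):
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass(frozen=True)
class LDInverse:
    """Moore–Penrose generalized inverse of an LD matrix."""

    snp_ids: tuple[str, ...]
    Rinv: np.ndarray
    rank: int


def compute_ld_matrix(panel, snp_ids: Sequence[str]) -> LDMatrix:
    """Pearson correlation of reference-panel dosages over the listed SNPs.

    Parameters
    ----------
    panel : GenotypeMatrix
        Reference-panel dosages (individuals x SNPs, coded 0/1/2).
    snp_ids : sequence of str
        SNPs to correlate, in the order they should appear in R.

    Raises
    ------
    KeyError
        If a requested SNP is absent from the panel.
    ValueError
        If the panel has fewer than two individuals, contains missing dosages,
        or a requested SNP has zero variance (correlation undefined).
    """
    snp_ids = tuple(snp_ids)
    idx = []
    for s in snp_ids:
        try:
            idx.append(panel.snp_index(s))
        except KeyError:
            raise KeyError(f"SNP {s!r} not present in reference panel") from None
    G = np.asarray(panel.dosages, dtype=float)[:, idx]
    if G.shape[0] < 2:
        raise ValueError("reference panel must contain at least 2 individuals")
    if np.isnan(G).any():
        raise ValueError("missing dosages are not supported")
    sd = G.std(axis=0)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise ValueError(
            f"zero-variance SNP(s) in reference panel: {[snp_ids[j] for j in zero]}"
        )
    if len(snp_ids) == 1:
        R = np.ones((1, 1))
    else:
        R = np.corrcoef(G, rowvar=False)
        # corrcoef can stray from exact symmetry / unit diagonal by rounding
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
        np.clip(R, -1.0, 1.0, out=R)
    return LDMatrix(snp_ids=snp_ids, R=R)


def generalized_inverse(ld: LDMatrix, tol: float = DEFAULT_TOL) -> LDInverse:
    """Moore–Penrose pseudoinverse of R via SVD.

    Singular values below ``tol`` times the largest singular value are treated as
    zero; the retained count is recorded as the effective rank. The pseudoinverse
    always exists, including for rank-deficient R (perfectly correlated SNPs).
    """
    R = np.asarray(ld.R, dtype=float)
    U, s, Vt = np.linalg.svd(R, hermitian=True)
    cutoff = tol * (s[0] if s.size else 0.0)
    keep = s > cutoff
    rank = int(keep.sum())
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    Rinv = (Vt.T * s_inv) @ U.T
    return LDInverse(snp_ids=ld.snp_ids, Rinv=Rinv, rank=rank)
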