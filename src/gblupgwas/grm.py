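"""Realized genomic relationship matrix (VanRaden method 1).

G = MM' / k with M the column-centered dosage matrix (dosage - 2p) and
k = 2 * sum_j p_j (1 - p_j).  Frequencies are estimated from the analyzed
sample itself, so M has zero column means, every row of G sums to zero and
1'G1 = 0.  Missing dosages are mean-imputed, i.e. become exactly 0 after
centering.

The same centered matrix M doubles as the W of the SNP-effect backsolve in
:mod:`gblupgwas.gwas`, which makes the GBLUP <-> SNP-BLUP equivalence
(M a_hat = u_hat) an exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = ["GRM", "CenteredGenotypes", "estimate_frequencies", "center", "build_grm", "stabilize", "grm_from_genotypes"]


@dataclass
class CenteredGenotypes:
    """M = dosages - 2p, missing entries imputed to 0."""

    M: np.ndarray
    freqs: np.ndarray
    snp_map: pd.DataFrame
    individual_ids: list[str]


@dataclass
class GRM:
    matrix: np.ndarray
    scaling_k: float
    freqs_used: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        if self.scaling_k <= 0:
            raise ValueError("scaling constant 2*sum(p(1-p)) must be positive")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.individual_ids, columns=self.individual_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path) -> "GRM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        mat = df.to_numpy(dtype=float)
        mat = 0.5 * (mat + mat.T)  # symmetrize away text-precision noise
        return cls(matrix=mat, scaling_k=np.nan, freqs_used=np.array([]),
                   individual_ids=[str(i) for i in df.index])


def estimate_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP allele frequency p = mean dosage / 2 over non-missing calls.

    Raises if any SNP is monomorphic or has no calls — run QC first.
    """
    n_called = np.sum(~np.isnan(g.dosages), axis=0)
    if (n_called == 0).any():
        j = int(np.argmax(n_called == 0))
        raise ValueError(f"SNP {g.snp_map['snp_id'].iloc[j]} has no genotype calls; apply QC first")
    p = np.nansum(g.dosages, axis=0) / (2.0 * n_called)
    if ((p == 0.0) | (p == 1.0)).any():
        j = int(np.argmax((p == 0.0) | (p == 1.0)))
        raise ValueError(
            f"monomorphic SNP {g.snp_map['snp_id'].iloc[j]} present; apply QC before building the GRM"
        )
    return p


def center(g: GenotypeMatrix, p: np.ndarray | None = None) -> CenteredGenotypes:
    """Center dosages to M = dosage - 2p; missing entries become exactly 0."""
    if p is None:
        p = estimate_frequencies(g)
    p = np.asarray(p, dtype=float)
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("frequencies must be strictly inside (0, 1)")
    dos = g.dosages.copy()
    miss = np.isnan(dos)
    if miss.any():
        dos[miss] = (2.0 * p)[np.where(miss)[1]]
    M = dos - 2.0 * p
    return CenteredGenotypes(M=M, freqs=p, snp_map=g.snp_map, individual_ids=list(g.individual_ids))


def build_grm(centered: CenteredGenotypes) -> GRM:
    """G = MM'/k, k = 2 sum p(1-p)."""
    p = centered.freqs
    k = float(2.0 * np.sum(p * (1.0 - p)))
    if k <= 0:
        raise ValueError("scaling constant is zero; all SNPs monomorphic?")
    n = centered.M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals for a relationship matrix")
    G = centered.M @ centered.M.T / k
    G = 0.5 * (G + G.T)
    return GRM(matrix=G, scaling_k=k, freqs_used=p, individual_ids=centered.individual_ids)


def stabilize(grm: GRM, blend_weight: float = 0.01) -> GRM:
    """Blend toward the identity, G* = (1-d)G + dI, to guarantee
    invertibility when n exceeds the marker rank."""
    d = blend_weight
    if not 0.0 <= d < 1.0:
        raise ValueError("blend_weight must be in [0, 1)")
    if d == 0.0:
        return grm
    n = grm.matrix.shape[0]
    return GRM(
        matrix=(1.0 - d) * grm.matrix + d * np.eye(n),
        scaling_k=grm.scaling_k,
        freqs_used=grm.freqs_used,
        individual_ids=grm.individual_ids,
    )


def grm_from_genotypes(g: GenotypeMatrix, blend_weight: float = 0.01) -> tuple[GRM, CenteredGenotypes]:
    """Convenience: frequencies -> centering -> G -> stabilized G."""
    centered = center(g)
    return stabilize(build_grm(centered), blend_weight), centered
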