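"""SNP-effect backsolving and windowed variance decomposition.

GEBV are converted to per-SNP marker effects with

    a_hat = D W' [W D W']^+ u_hat

where W is the centered genotype matrix (the same M used for the GRM) and D
a diagonal SNP-weight matrix (identity by default, i.e. unweighted).  The
pseudoinverse uses a symmetric eigendecomposition with a relative eigenvalue
cutoff, so rank deficiency (n individuals << m SNPs, centered rows) is
handled exactly; with D = I and u_hat in the column space of W the projection
identity W a_hat = u_hat holds to machine precision.

Additive genetic variance is then attributed to windows of (by default) 10
adjacent SNPs: the window genetic value u_i = sum_{j in window} W_j a_hat_j
is computed per individual and its sample variance expressed as a percentage
of the trait's REML additive variance.  Windows above a percentage threshold
(default 0.30%) are merged into candidate QTL regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import CenteredGenotypes

__all__ = [
    "SNPEffectSet",
    "QTLRegion",
    "backsolve_snp_effects",
    "window_variances",
    "select_regions",
    "window_length",
]


@dataclass
class SNPEffectSet:
    a_hat: np.ndarray
    snp_map: pd.DataFrame
    weights: np.ndarray | None = None  # None = identity D

    def __post_init__(self) -> None:
        if len(self.a_hat) != len(self.snp_map):
            raise ValueError("effect vector and SNP map length differ")
        if not np.isfinite(self.a_hat).all():
            raise ValueError("non-finite SNP effects")


@dataclass
class QTLRegion:
    chrom: str
    start_bp: int
    end_bp: int
    max_pct: float
    contributing_windows: list[int]

    @property
    def length_bp(self) -> int:
        return window_length(self.start_bp, self.end_bp)


def _pinv_psd(A: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """Pseudoinverse of a symmetric PSD matrix via eigendecomposition with a
    relative eigenvalue cutoff."""
    w, U = np.linalg.eigh(0.5 * (A + A.T))
    cut = rcond * max(w.max(), 0.0)
    inv_w = np.where(w > cut, 1.0 / np.where(w > cut, w, 1.0), 0.0)
    return (U * inv_w) @ U.T


def backsolve_snp_effects(
    centered: CenteredGenotypes,
    u_hat: np.ndarray,
    weights: np.ndarray | None = None,
    rcond: float = 1e-10,
) -> SNPEffectSet:
    """a_hat = D W' (W D W')^+ u_hat with W = centered.M."""
    M = centered.M
    u = np.asarray(u_hat, dtype=float).ravel()
    if u.shape[0] != M.shape[0]:
        raise ValueError(f"u_hat length {u.shape[0]} != {M.shape[0]} individuals")
    if weights is None:
        WDWt = M @ M.T
        a = M.T @ (_pinv_psd(WDWt, rcond) @ u)
    else:
        D = np.asarray(weights, dtype=float).ravel()
        if D.shape[0] != M.shape[1]:
            raise ValueError("weights length must equal number of SNPs")
        if (D <= 0).any():
            raise ValueError("SNP weights must be positive")
        WDWt = (M * D) @ M.T
        a = D * (M.T @ (_pinv_psd(WDWt, rcond) @ u))
    return SNPEffectSet(a_hat=a, snp_map=centered.snp_map, weights=weights)


def window_variances(
    centered: CenteredGenotypes,
    effects: SNPEffectSet,
    sigma2_u: float,
    window_size: int = 10,
    mode: str = "sliding",
) -> pd.DataFrame:
    """Percentage of additive genetic variance per window of adjacent SNPs.

    pct = 100 * Var(sum_{j in window} W_j a_hat_j) / sigma2_u, with the
    sample variance (n-1 denominator) taken across individuals.  Windows
    never span chromosomes; ``sliding`` advances one SNP at a time,
    ``blocked`` by ``window_size`` (the trailing window may be shorter).

    Returns a frame with chrom, start_snp_index (into the SNP map),
    start_bp, end_bp, n_snps, pct, sorted by (chrom, start_bp).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if sigma2_u <= 0:
        raise ValueError("sigma2_u must be positive")
    if mode not in ("sliding", "blocked"):
        raise ValueError(f"unknown mode {mode!r}")
    M = centered.M
    a = effects.a_hat
    snp_map = centered.snp_map
    # per-individual cumulative genetic value along the SNP axis
    C = np.cumsum(M * a, axis=1)
    C = np.concatenate([np.zeros((M.shape[0], 1)), C], axis=1)
    rows = []
    for chrom, idx in snp_map.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        lo, hi = idx[0], idx[-1] + 1
        m_chr = hi - lo
        starts = range(0, max(m_chr - window_size, 0) + 1) if mode == "sliding" else range(0, m_chr, window_size)
        if mode == "sliding" and m_chr < window_size:
            starts = range(1)  # a single short window covering the chromosome
        for s in starts:
            e = min(s + window_size, m_chr)
            vals = C[:, lo + e] - C[:, lo + s]
            pct = 100.0 * float(np.var(vals, ddof=1)) / sigma2_u
            rows.append(
                (
                    str(chrom),
                    int(lo + s),
                    int(snp_map["bp"].iloc[lo + s]),
                    int(snp_map["bp"].iloc[lo + e - 1]),
                    e - s,
                    pct,
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start_snp_index", "start_bp", "end_bp", "n_snps", "pct"]
    )


def select_regions(windows: pd.DataFrame, threshold_pct: float = 0.30) -> list[QTLRegion]:
    """Merge suprathreshold windows into QTL regions.

    Windows with pct >= threshold are kept; kept windows on the same
    chromosome whose bp intervals overlap or touch are merged into one
    region carrying the maximum window percentage.
    """
    kept = windows.loc[windows["pct"] >= threshold_pct].sort_values(["chrom", "start_bp"])
    regions: list[QTLRegion] = []
    for _, row in kept.iterrows():
        if (
            regions
            and regions[-1].chrom == str(row["chrom"])
            and int(row["start_bp"]) <= regions[-1].end_bp + 1
        ):
            last = regions[-1]
            last.end_bp = max(last.end_bp, int(row["end_bp"]))
            last.max_pct = max(last.max_pct, float(row["pct"]))
            last.contributing_windows.append(int(row.name))
        else:
            regions.append(
                QTLRegion(
                    chrom=str(row["chrom"]),
                    start_bp=int(row["start_bp"]),
                    end_bp=int(row["end_bp"]),
                    max_pct=float(row["pct"]),
                    contributing_windows=[int(row.name)],
                )
            )
    regions.sort(key=lambda r: ((0, int(r.chrom)) if r.chrom.isdigit() else (1, r.chrom), r.start_bp))
    return regions


def window_length(start_bp: int, end_bp: int) -> int:
    """Window extent end - start in bp (the convention used when reporting
    genomic window lengths)."""
    if end_bp < start_bp:
        raise ValueError(f"reversed window coordinates: {start_bp} > {end_bp}")
    return int(end_bp) - int(start_bp)


def regions_to_bed(regions: list[QTLRegion]) -> pd.DataFrame:
    """QTL regions as 0-based half-open BED records."""
    return pd.DataFrame(
        [(r.chrom, r.start_bp - 1, r.end_bp, f"qtl_region_{i+1}", r.max_pct)
         for i, r in enumerate(regions)],
        columns=["chrom", "start", "end", "name", "max_pct"],
    )
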