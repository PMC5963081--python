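"""SNP quality control.

Filters, applied in a fixed reporting order (sex chromosomes, monomorphic,
minor allele frequency, call rate, Hardy-Weinberg heterozygosity deviation),
with every removal attributed to the first filter it violates.  All
thresholds are strict: a SNP sitting exactly on a boundary is kept.

The Hardy-Weinberg screen is the absolute difference between observed and
expected (2p(1-p)) heterozygote frequency; an exact HWE test is deliberately
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = ["QCThresholds", "QCReport", "snp_statistics", "apply_qc"]

FILTER_ORDER = ("sex_chrom", "monomorphic", "maf", "call_rate", "hwe_dev")


@dataclass
class QCThresholds:
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    hwe_het_dev_max: float = 0.15
    drop_sex_chroms: bool = True
    drop_monomorphic: bool = True
    individual_call_rate_min: float = 0.90
    drop_low_call_individuals: bool = False


@dataclass
class QCReport:
    n_snps_in: int
    n_snps_out: int
    n_individuals: int
    removal_counts: dict[str, int]
    snp_fate: pd.DataFrame  # snp_id, fate ('kept' or the removing filter)
    individuals_removed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        removed = sum(self.removal_counts.values())
        assert self.n_snps_out + removed == self.n_snps_in, "QC report does not conserve SNPs"

    def to_tsv(self, path) -> None:
        self.snp_fate.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [
            "SNP quality control (HWE screened as |observed - expected| heterozygote "
            "frequency, absolute value)",
            f"SNPs in: {self.n_snps_in}   SNPs retained: {self.n_snps_out}   "
            f"individuals: {self.n_individuals}",
        ]
        for name in FILTER_ORDER:
            lines.append(f"  removed by {name}: {self.removal_counts.get(name, 0)}")
        if self.individuals_removed:
            lines.append(f"  individuals removed (call rate): {len(self.individuals_removed)}")
        return "\n".join(lines)


def snp_statistics(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP allele frequency, MAF, call rate, and observed/expected
    heterozygosity, computed over non-missing calls.

    A SNP with zero calls gets call_rate 0 and NaN frequency statistics.
    """
    dos = g.dosages
    n = dos.shape[0]
    n_called = np.sum(~np.isnan(dos), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_called > 0, np.nansum(dos, axis=0) / (2.0 * np.maximum(n_called, 1)), np.nan)
        het_obs = np.where(n_called > 0, np.nansum(dos == 1.0, axis=0) / np.maximum(n_called, 1), np.nan)
    het_exp = 2.0 * freq * (1.0 - freq)
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame(
        {
            "snp_id": g.snp_map["snp_id"],
            "chrom": g.snp_map["chrom"],
            "allele_freq": freq,
            "maf": maf,
            "call_rate": n_called / n,
            "het_obs": het_obs,
            "het_exp": het_exp,
        }
    )


def apply_qc(g: GenotypeMatrix, t: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the SNP filters and return the retained matrix plus a report.

    Strict boundaries: removed iff maf < maf_min, call rate < call_rate_min,
    or |het_obs - het_exp| > hwe_het_dev_max.
    """
    t = t or QCThresholds()
    g_work = g
    individuals_removed: list[str] = []
    if t.drop_low_call_individuals:
        ind_cr = np.mean(~np.isnan(g.dosages), axis=1)
        keep_ind = ind_cr >= t.individual_call_rate_min
        if not keep_ind.all():
            individuals_removed = [i for i, k in zip(g.individual_ids, keep_ind) if not k]
            from dataclasses import replace

            g_work = replace(
                g,
                dosages=g.dosages[keep_ind].copy(),
                individual_ids=[i for i, k in zip(g.individual_ids, keep_ind) if k],
            )

    stats = snp_statistics(g_work)
    m = g_work.n_snps
    fate = np.full(m, "kept", dtype=object)
    chrom = g_work.snp_map["chrom"].astype(str).to_numpy()

    is_sex = np.isin(chrom, list(g_work.sex_chrom_labels))
    freq = stats["allele_freq"].to_numpy()
    mono = np.isfinite(freq) & ((freq == 0.0) | (freq == 1.0))
    # strict boundaries with a 1e-9 guard so counts landing exactly on a
    # threshold (e.g. het deviation 26/40 - 0.5 = 0.15) are kept despite
    # binary-representation noise
    eps = 1e-9
    maf_bad = stats["maf"].to_numpy() < t.maf_min - eps  # NaN compares False
    cr_bad = stats["call_rate"].to_numpy() < t.call_rate_min - eps
    dev = np.abs(stats["het_obs"].to_numpy() - stats["het_exp"].to_numpy())
    hwe_bad = dev > t.hwe_het_dev_max + eps

    checks = [
        ("sex_chrom", is_sex if t.drop_sex_chroms else np.zeros(m, bool)),
        ("monomorphic", mono if t.drop_monomorphic else np.zeros(m, bool)),
        ("maf", maf_bad),
        ("call_rate", cr_bad),
        ("hwe_dev", hwe_bad),
    ]
    for name, bad in checks:
        hit = bad & (fate == "kept")
        fate[hit] = name

    keep = fate == "kept"
    if not keep.any():
        raise ValueError(
            "quality control removed every SNP; review thresholds "
            f"(maf_min={t.maf_min}, call_rate_min={t.call_rate_min}, "
            f"hwe_het_dev_max={t.hwe_het_dev_max})"
        )
    report = QCReport(
        n_snps_in=m,
        n_snps_out=int(keep.sum()),
        n_individuals=g_work.n_individuals,
        removal_counts={name: int((fate == name).sum()) for name in FILTER_ORDER},
        snp_fate=pd.DataFrame({"snp_id": g_work.snp_map["snp_id"], "fate": fate}),
        individuals_removed=individuals_removed,
    )
    return g_work.subset_snps(keep), report
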