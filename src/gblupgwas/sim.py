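"""Synthetic genotype/phenotype simulation with known truth.

Emulates a small livestock study population: a few hundred genotyped males
with a mixture of full-sib, half-sib and unrelated individuals, ~50k SNP-chip
autosomal markers, contemporary-group fixed effects, and additive polygenic
traits with chosen heritabilities and genetic/residual correlations to an
anchor trait (intramuscular fat).  Every quantity needed to test the
downstream pipeline (true breeding values, QTL positions and effects,
realized heritability) is returned alongside the data.

Founder haplotypes are drawn under Hardy-Weinberg at per-SNP allele
frequencies; linkage disequilibrium, when requested, comes from a first-order
Markov copying process along each chromosome (``ld_decay`` = probability of
copying the previous allele; 0 gives linkage equilibrium).  Sib families are
produced by gene-dropping: each offspring receives one whole-chromosome
haplotype from each parent (no intra-chromosome recombination).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, write_plink_text, write_tsv_dosage, write_phenotypes

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_phenotypes",
    "write_fixture",
    "study_config",
]


@dataclass
class TraitSpec:
    """Target moments and architecture for one simulated trait.

    The first trait in ``SimulationConfig.trait_specs`` acts as the anchor;
    correlations of later traits are expressed against it.
    """

    name: str
    mean: float
    h2_true: float
    phenotypic_var: float
    n_qtl: int = 300
    genetic_corr_with_anchor: float = 0.0
    residual_corr_with_anchor: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError(f"h2_true must be in [0,1], got {self.h2_true}")
        for r in (self.genetic_corr_with_anchor, self.residual_corr_with_anchor):
            if abs(r) > 1.0:
                raise ValueError(f"correlation out of [-1,1]: {r}")
        if self.phenotypic_var <= 0:
            raise ValueError("phenotypic_var must be positive")
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")


@dataclass
class SimulationConfig:
    n_individuals: int = 216
    n_snps: int = 54241
    n_chromosomes: int = 26
    allele_freq_range: tuple[float, float] = (0.01, 0.5)
    family_structure: Sequence[tuple[str, int]] = (
        ("full_sib", 96),
        ("half_sib", 72),
        ("unrelated", 48),
    )
    sib_family_size: int = 8
    n_groups: int = 14
    group_size_range: tuple[int, int] = (6, 20)
    trait_specs: Sequence[TraitSpec] = ()
    ld_decay: float = 0.0
    missing_rate: float = 0.0
    group_var_fraction: float = 0.25
    seed: int = 0
    snp_freqs: np.ndarray | None = None  # explicit per-SNP frequencies (overrides range)

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("need at least one individual and one SNP")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"allele_freq_range must lie within (0, 0.5], got {self.allele_freq_range}")
        if sum(c for _, c in self.family_structure) != self.n_individuals:
            raise ValueError("family_structure counts must sum to n_individuals")
        for kind, _ in self.family_structure:
            if kind not in ("full_sib", "half_sib", "unrelated"):
                raise ValueError(f"unknown family type {kind!r}")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        glo, ghi = self.group_size_range
        if not (1 <= glo <= ghi):
            raise ValueError("invalid group_size_range")
        if not glo * self.n_groups <= self.n_individuals <= ghi * self.n_groups:
            raise ValueError("group sizes cannot sum to n_individuals under group_size_range")


@dataclass
class TruthRecord:
    """Ground truth of a phenotype simulation, for recovery tests."""

    true_breeding_values: pd.DataFrame  # index individual id, one column per trait
    qtl_indices: dict[str, np.ndarray]
    qtl_effects: dict[str, np.ndarray]
    realized_h2: dict[str, float]


def _scaled_structure(n: int) -> dict:
    """Family mixture and contemporary-group layout scaled to n individuals,
    keeping the study proportions (~44% full sibs, ~33% half sibs, rest
    unrelated; groups of 6-20 averaging ~15)."""
    fs = max(2 * (round(0.44 * n) // 2), 0)
    hs = max(2 * (round(0.33 * n) // 2), 0)
    if fs < 2 or hs < 2 or n < 8:
        fam: tuple = (("unrelated", n),)
    else:
        fam = (("full_sib", fs), ("half_sib", hs), ("unrelated", n - fs - hs))
    n_groups = max(1, round(n / 15))
    lo = max(1, min(6, n // n_groups))
    hi = max(lo, -(-n // n_groups) + lo)  # ceil(n/k) + slack keeps it feasible
    return {"family_structure": fam, "n_groups": n_groups, "group_size_range": (lo, hi)}


def study_config(**overrides) -> SimulationConfig:
    """The default study-scale scenario: 216 males in 14 contemporary groups,
    ~54k chip SNPs on 26 autosomes, an intramuscular-fat anchor trait plus
    two fatty-acid-like traits with moderate heritabilities.  Overriding
    ``n_individuals`` without an explicit family/group layout rescales the
    default mixture proportionally."""
    n = overrides.get("n_individuals", 216)
    if n != 216:
        derived = _scaled_structure(n)
        for key, val in derived.items():
            overrides.setdefault(key, val)
    traits = overrides.pop(
        "trait_specs",
        (
            TraitSpec("IMF", mean=3.46, h2_true=0.30, phenotypic_var=0.769**2),
            TraitSpec(
                "C18_0", mean=20.29, h2_true=0.30, phenotypic_var=3.342**2,
                genetic_corr_with_anchor=0.3, residual_corr_with_anchor=0.2,
            ),
            TraitSpec(
                "C14_0", mean=2.21, h2_true=0.44, phenotypic_var=0.752**2,
                genetic_corr_with_anchor=0.3, residual_corr_with_anchor=0.2,
            ),
        ),
    )
    return SimulationConfig(trait_specs=traits, **overrides)


# ---------------------------------------------------------------------------
# Genotypes


def _draw_haplotypes(n_hap: int, freqs: np.ndarray, chrom_bounds: list[tuple[int, int]],
                     ld_decay: float, rng: np.random.Generator) -> np.ndarray:
    """0/1 haplotype matrix (n_hap x m)."""
    m = freqs.size
    if ld_decay == 0.0:
        return (rng.random((n_hap, m)) < freqs).astype(np.int8)
    hap = np.empty((n_hap, m), dtype=np.int8)
    for start, stop in chrom_bounds:
        hap[:, start] = rng.random(n_hap) < freqs[start]
        for j in range(start + 1, stop):
            fresh = (rng.random(n_hap) < freqs[j]).astype(np.int8)
            copy = rng.random(n_hap) < ld_decay
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    return hap


def _chrom_layout(n_snps: int, n_chrom: int, rng: np.random.Generator):
    """Assign SNPs to chromosomes (near-equal blocks) with increasing bp."""
    sizes = np.full(n_chrom, n_snps // n_chrom)
    sizes[: n_snps % n_chrom] += 1
    sizes = sizes[sizes > 0]
    chroms, bps, bounds = [], [], []
    start = 0
    for c, sz in enumerate(sizes, start=1):
        gaps = rng.integers(1, 100_000, size=sz)
        bp = np.cumsum(gaps)
        chroms.extend([str(c)] * sz)
        bps.extend(bp.tolist())
        bounds.append((start, start + sz))
        start += sz
    return chroms, bps, bounds


def _family_sizes(count: int, family_size: int) -> list[int]:
    """Split a type count into sib families of ``family_size`` (the last
    family absorbs the remainder; a remainder of 1 joins the last family)."""
    if count < 2:
        raise ValueError("sib family types need a count of at least 2")
    family_size = max(2, family_size)
    sizes = [family_size] * (count // family_size)
    rem = count % family_size
    if rem >= 2:
        sizes.append(rem)
    elif rem == 1:
        if sizes:
            sizes[-1] += 1
        else:
            sizes = [count]
    return sizes


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a dosage matrix under the configured family structure.

    Founders follow HWE at per-SNP frequencies drawn uniformly from
    ``allele_freq_range`` (or taken from ``config.snp_freqs``); sib families
    are gene-dropped from freshly drawn parents.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    if config.snp_freqs is not None:
        freqs = np.asarray(config.snp_freqs, dtype=float)
        if freqs.size != m:
            raise ValueError("snp_freqs length must equal n_snps")
        if ((freqs < 0) | (freqs > 1)).any():
            raise ValueError("snp_freqs must be in [0,1]")
    else:
        lo, hi = config.allele_freq_range
        freqs = rng.uniform(lo, hi, size=m)
    chroms, bps, bounds = _chrom_layout(m, config.n_chromosomes, rng)

    # count founder haplotypes first so they can be drawn in one batch
    # (the Markov LD walk is vectorized across haplotypes)
    n_founder_haps = 0
    for kind, count in config.family_structure:
        if kind == "unrelated":
            n_founder_haps += 2 * count
        elif kind == "full_sib":
            n_founder_haps += 4 * len(_family_sizes(count, config.sib_family_size))
        elif kind == "half_sib":
            for fam in _family_sizes(count, config.sib_family_size):
                n_founder_haps += 2 + 2 * fam  # sire + one dam per offspring
    pool = _draw_haplotypes(n_founder_haps, freqs, bounds, config.ld_decay, rng)
    cursor = 0

    def haps(k: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor : cursor + k]
        cursor += k
        return out

    def drop_child(par1: np.ndarray, par2: np.ndarray) -> np.ndarray:
        # one whole-chromosome haplotype from each parent
        child = np.empty(m, dtype=np.int8)
        for start, stop in bounds:
            child[start:stop] = (
                par1[rng.integers(2), start:stop] + par2[rng.integers(2), start:stop]
            )
        return child

    rows: list[np.ndarray] = []
    for kind, count in config.family_structure:
        if kind == "unrelated":
            h = haps(2 * count)
            rows.extend(h[2 * i] + h[2 * i + 1] for i in range(count))
        elif kind == "full_sib":
            for fam in _family_sizes(count, config.sib_family_size):
                parents = haps(4).reshape(2, 2, m)
                rows.extend(drop_child(parents[0], parents[1]) for _ in range(fam))
        elif kind == "half_sib":
            for fam in _family_sizes(count, config.sib_family_size):
                sire = haps(2)
                rows.extend(drop_child(sire, haps(2)) for _ in range(fam))
    dosages = np.vstack(rows).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    snp_map = pd.DataFrame(
        {"snp_id": [f"snp{j + 1:06d}" for j in range(m)], "chrom": chroms, "bp": bps}
    )
    ids = [f"ind{i + 1:04d}" for i in range(config.n_individuals)]
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map, individual_ids=ids)


# ---------------------------------------------------------------------------
# Phenotypes


def _group_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.group_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_groups)
    # repair to the exact total while staying inside [lo, hi]
    diff = config.n_individuals - int(sizes.sum())
    while diff != 0:
        i = rng.integers(config.n_groups)
        step = 1 if diff > 0 else -1
        if lo <= sizes[i] + step <= hi:
            sizes[i] += step
            diff -= step
    return sizes


def _scaled_genetic_value(M: np.ndarray, qtl: np.ndarray, effects: np.ndarray,
                          target_var: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear genetic value from QTL effects, rescaled so its sample variance
    equals ``target_var`` exactly; returns (values, rescaled effects)."""
    u = M[:, qtl] @ effects
    v = u.var(ddof=1)
    if target_var == 0.0:
        return np.zeros_like(u), np.zeros_like(effects)
    if v == 0.0:
        raise ValueError("QTL genetic value has zero variance; pick polymorphic QTL")
    scale = np.sqrt(target_var / v)
    return u * scale, effects * scale


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=1)
    return x / s if s > 0 else x


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate trait observations ``y = mean + group + u + e`` on top of a
    genotype matrix, honouring each TraitSpec's heritability and its
    genetic/residual correlation with the anchor (first) trait.

    Breeding values are built from ``n_qtl`` marker effects on the centered
    dosages and rescaled so the sample genetic variance hits
    ``h2_true * phenotypic_var`` exactly; correlated traits combine the
    anchor's standardized breeding value with an independent own-QTL part.
    """
    if not config.trait_specs:
        raise ValueError("config.trait_specs must not be empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n, m = genotypes.dosages.shape
    dos = genotypes.dosages.copy()
    p = np.nanmean(dos, axis=0) / 2.0
    inds = np.where(np.isnan(dos))
    dos[inds] = 2.0 * p[inds[1]]
    M = dos - 2.0 * p

    sizes = _group_sizes(config, rng)
    labels = np.repeat([f"G{g + 1:02d}" for g in range(config.n_groups)], sizes)
    rng.shuffle(labels)

    polymorphic = np.flatnonzero(np.nanvar(genotypes.dosages, axis=0) > 0)
    if polymorphic.size == 0:
        raise ValueError("no polymorphic SNPs to place QTL on")

    # implied 2x2 H and R against the anchor must be PSD, i.e. |r| <= 1
    table: dict[str, np.ndarray] = {}
    truth_u: dict[str, np.ndarray] = {}
    qtl_idx: dict[str, np.ndarray] = {}
    qtl_eff: dict[str, np.ndarray] = {}
    realized: dict[str, float] = {}
    anchor_u_std: np.ndarray | None = None
    anchor_e_std: np.ndarray | None = None

    for t, spec in enumerate(config.trait_specs):
        sig_u2 = spec.h2_true * spec.phenotypic_var
        sig_e2 = (1.0 - spec.h2_true) * spec.phenotypic_var
        qtl = np.sort(rng.choice(polymorphic, size=min(spec.n_qtl, polymorphic.size), replace=False))
        raw_eff = rng.normal(size=qtl.size)
        u_own, eff = _scaled_genetic_value(M, qtl, raw_eff, sig_u2 if sig_u2 > 0 else 0.0)
        e_own = rng.normal(0.0, 1.0, size=n)
        if t == 0:
            u, e = u_own, e_own * np.sqrt(sig_e2)
            anchor_u_std = _standardize(u) if u.std(ddof=1) > 0 else None
            anchor_e_std = _standardize(e) if e.std(ddof=1) > 0 else None
        else:
            rg = spec.genetic_corr_with_anchor
            re_ = spec.residual_corr_with_anchor
            if rg != 0.0 and anchor_u_std is not None and sig_u2 > 0:
                mix = rg * anchor_u_std + np.sqrt(1 - rg**2) * _standardize(u_own)
                u = mix * np.sqrt(sig_u2) / mix.std(ddof=1)
                eff = eff * np.sqrt(1 - rg**2)  # own-QTL share of the mix
            else:
                u = u_own
            if re_ != 0.0 and anchor_e_std is not None and sig_e2 > 0:
                e = (re_ * anchor_e_std + np.sqrt(1 - re_**2) * e_own) * np.sqrt(sig_e2)
            else:
                e = e_own * np.sqrt(sig_e2)
        group_eff = rng.normal(
            0.0, np.sqrt(config.group_var_fraction * spec.phenotypic_var), size=config.n_groups
        )
        g_of = pd.Series(group_eff, index=[f"G{g + 1:02d}" for g in range(config.n_groups)])
        y = spec.mean + g_of[labels].to_numpy() + u + e
        table[spec.name] = y
        truth_u[spec.name] = u
        qtl_idx[spec.name] = qtl
        qtl_eff[spec.name] = eff
        denom = np.var(u + e, ddof=1)
        realized[spec.name] = float(u.var(ddof=1) / denom) if denom > 0 else 0.0

    phen = pd.DataFrame({"id": genotypes.individual_ids, "group": labels, **table})
    truth = TruthRecord(
        true_breeding_values=pd.DataFrame(truth_u, index=genotypes.individual_ids),
        qtl_indices=qtl_idx,
        qtl_effects=qtl_eff,
        realized_h2=realized,
    )
    return phen, truth


# ---------------------------------------------------------------------------
# Fixture files


def write_fixture(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    truth: TruthRecord | None,
    directory: str | Path,
    dialect: str = "plink_text",
) -> dict[str, Path]:
    """Write the simulated data set as plain-text files that round-trip
    through the io readers.  Returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if dialect == "plink_text":
        write_plink_text(genotypes, directory / "genotypes")
        paths["ped"] = directory / "genotypes.ped"
        paths["map"] = directory / "genotypes.map"
    elif dialect == "tsv_dosage":
        paths["dosage"] = directory / "genotypes.tsv"
        paths["map"] = directory / "genotypes.snpmap.tsv"
        write_tsv_dosage(genotypes, paths["dosage"], paths["map"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    paths["phenotypes"] = directory / "phenotypes.tsv"
    write_phenotypes(phenotypes, paths["phenotypes"])
    if truth is not None:
        paths["truth_bv"] = directory / "truth_breeding_values.tsv"
        truth.true_breeding_values.rename_axis("id").reset_index().to_csv(
            paths["truth_bv"], sep="\t", index=False, float_format="%.10g"
        )
        rows = []
        for trait, idx in truth.qtl_indices.items():
            for i, eff in zip(idx, truth.qtl_effects[trait]):
                rows.append((trait, genotypes.snp_map["snp_id"].iloc[i], int(i), eff))
        paths["truth_qtl"] = directory / "truth_qtl.tsv"
        pd.DataFrame(rows, columns=["trait", "snp_id", "snp_index", "effect"]).to_csv(
            paths["truth_qtl"], sep="\t", index=False, float_format="%.10g"
        )
        paths["truth_h2"] = directory / "truth_realized_h2.tsv"
        pd.DataFrame(
            {"trait": list(truth.realized_h2), "realized_h2": list(truth.realized_h2.values())}
        ).to_csv(paths["truth_h2"], sep="\t", index=False, float_format="%.10g")
    return paths
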