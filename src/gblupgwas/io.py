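"""Genotype and phenotype file input/output.

Two on-disk genotype dialects are supported:

* ``plink_text`` — classic PLINK ``.ped``/``.map`` pair.  The ``.ped`` carries
  six leading columns (family id, individual id, sire, dam, sex, phenotype)
  followed by two allele calls per SNP; alleles are written as ``A``/``B`` and
  a missing genotype as ``0 0``.  Dosage is the count of the ``A`` allele.
* ``tsv_dosage`` — a plain table with an ``id`` column followed by one column
  per SNP holding dosages 0/1/2 with ``NA`` for missing, accompanied by a SNP
  map TSV (``snp_id``, ``chrom``, ``bp``).

Phenotypes travel as a TSV with ``id``, ``group`` and one column per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "write_plink_text",
    "write_tsv_dosage",
    "read_phenotypes",
    "write_phenotypes",
]

DEFAULT_SEX_CHROMS = frozenset({"X", "Y", "x", "y"})


def _chrom_sort_key(label: str):
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def _map_order(snp_map: pd.DataFrame) -> list[int]:
    return sorted(
        range(len(snp_map)),
        key=lambda j: (_chrom_sort_key(snp_map["chrom"].iloc[j]), snp_map["bp"].iloc[j]),
    )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with its SNP map.

    ``dosages`` is a float array with entries in {0, 1, 2} and NaN marking a
    missing call.  ``snp_map`` has columns ``snp_id``, ``chrom``, ``bp``
    (1-based position) and is sorted by (chrom, bp).
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    individual_ids: list[str]
    sex_chrom_labels: frozenset = field(default_factory=lambda: DEFAULT_SEX_CHROMS)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs array")
        n, m = self.dosages.shape
        if n == 0 or m == 0:
            raise ValueError("genotype matrix must have at least one individual and one SNP")
        if len(self.individual_ids) != n:
            raise ValueError(f"{len(self.individual_ids)} ids for {n} matrix rows")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicated individual ids")
        if len(self.snp_map) != m:
            raise ValueError(f"snp_map has {len(self.snp_map)} rows for {m} SNP columns")
        required = {"snp_id", "chrom", "bp"}
        if not required.issubset(self.snp_map.columns):
            raise ValueError(f"snp_map must have columns {sorted(required)}")
        if self.snp_map["snp_id"].duplicated().any():
            dup = self.snp_map.loc[self.snp_map["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicated SNP id: {dup}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage entries must be 0/1/2/missing; found {bad}")
        keys = [(_chrom_sort_key(c), b) for c, b in zip(self.snp_map["chrom"], self.snp_map["bp"])]
        if keys != sorted(keys):
            raise ValueError("snp_map must be sorted by (chrom, bp)")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the SNP columns selected by ``keep``
        (boolean mask or integer index array, in map order)."""
        keep = np.asarray(keep)
        return replace(
            self,
            dosages=self.dosages[:, keep].copy(),
            snp_map=self.snp_map.iloc[np.flatnonzero(keep) if keep.dtype == bool else keep]
            .reset_index(drop=True)
            .copy(),
        )


# ---------------------------------------------------------------------------
# PLINK text dialect


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 columns in .map, got {len(parts)}")
        chrom, snp_id, _cm, bp = parts
        rows.append((snp_id, chrom, int(bp)))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "bp"])


def _read_plink_text(prefix: Path, counted_allele: str = "A") -> GenotypeMatrix:
    snp_map = _read_map(prefix.with_suffix(".map"))
    m = len(snp_map)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for ln, line in enumerate(prefix.with_suffix(".ped").read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ValueError(
                f"{prefix.with_suffix('.ped')}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
            )
        ids.append(parts[1])
        alleles = parts[6:]
        dos = np.empty(m)
        for j in range(m):
            a1, a2 = alleles[2 * j], alleles[2 * j + 1]
            if a1 == "0" or a2 == "0":
                dos[j] = np.nan
            else:
                dos[j] = (a1 == counted_allele) + (a2 == counted_allele)
        rows.append(dos)
    order = _map_order(snp_map)
    snp_map = snp_map.iloc[order].reset_index(drop=True)
    dosages = np.vstack(rows)[:, order]
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map, individual_ids=ids)


def write_plink_text(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix``.ped/.map; dosage = count of allele ``A``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in g.snp_map.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.bp}\n")
    pair = {0.0: "B B", 1.0: "A B", 2.0: "A A"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(g.individual_ids):
            calls = " ".join(
                "0 0" if np.isnan(d) else pair[d] for d in g.dosages[i]
            )
            fh.write(f"FAM {ind} 0 0 1 -9 {calls}\n")


# ---------------------------------------------------------------------------
# TSV dosage dialect


def _read_tsv_dosage(geno_path: Path, map_path: Path) -> GenotypeMatrix:
    geno = pd.read_csv(geno_path, sep="\t", dtype={"id": str})
    if "id" not in geno.columns:
        raise ValueError(f"{geno_path}: first column must be 'id'")
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"snp_id": str, "chrom": str, "bp": int})
    snp_ids = [c for c in geno.columns if c != "id"]
    if list(snp_map["snp_id"]) != snp_ids:
        # allow map in any order; align columns to map order
        missing = set(snp_map["snp_id"]) ^ set(snp_ids)
        if missing:
            raise ValueError(f"SNP ids differ between {geno_path} and {map_path}: {sorted(missing)[:5]}")
    order = _map_order(snp_map)
    snp_map = snp_map.iloc[order].reset_index(drop=True)
    dosages = geno[snp_map["snp_id"].tolist()].to_numpy(dtype=float)
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map, individual_ids=geno["id"].tolist())


def write_tsv_dosage(g: GenotypeMatrix, geno_path: str | Path, map_path: str | Path) -> None:
    """Write the dosage table (``NA`` = missing) and SNP map as TSV."""
    geno_path, map_path = Path(geno_path), Path(map_path)
    geno_path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(g.dosages, columns=g.snp_map["snp_id"].tolist())
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "id", g.individual_ids)
    df.to_csv(geno_path, sep="\t", index=False)
    g.snp_map[["snp_id", "chrom", "bp"]].to_csv(map_path, sep="\t", index=False)


def read_genotypes(
    path: str | Path,
    dialect: str = "plink_text",
    map_path: str | Path | None = None,
    counted_allele: str = "A",
) -> GenotypeMatrix:
    """Read a genotype matrix.

    Parameters
    ----------
    path
        For ``plink_text``, the file prefix (``.ped``/``.map`` appended).
        For ``tsv_dosage``, the dosage table path.
    dialect
        ``plink_text`` or ``tsv_dosage``.
    map_path
        SNP map TSV, required for ``tsv_dosage``.
    counted_allele
        Which allele a dosage counts in the PLINK dialect.
    """
    path = Path(path)
    if dialect == "plink_text":
        return _read_plink_text(path, counted_allele=counted_allele)
    if dialect == "tsv_dosage":
        if map_path is None:
            map_path = path.with_name(path.stem + ".snpmap.tsv")
        return _read_tsv_dosage(path, Path(map_path))
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Phenotypes


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "group": str})
    for col in ("id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: phenotype table must have an '{col}' column")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
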