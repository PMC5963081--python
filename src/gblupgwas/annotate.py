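"""Positional candidate-gene lookup for QTL regions.

Gene intervals come from a BED file (0-based half-open, converted on read)
or a minimal GFF3 (only ``gene`` records, ``ID`` attribute as the gene id).
Internally everything is 1-based inclusive, matching the convention in which
genomic window coordinates are reported; a gene is a hit for a region when
the closed intervals share at least one base pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .gwas import QTLRegion

__all__ = ["GeneInterval", "RegionGeneHit", "read_annotation", "overlap_genes"]


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start {self.start_bp} > end {self.end_bp}")


@dataclass
class RegionGeneHit:
    region: QTLRegion
    gene_id: str
    overlap_bp: int


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for piece in attr.strip().split(";"):
        if "=" in piece:
            k, v = piece.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(path: str | Path, format: str = "bed") -> list[GeneInterval]:
    """Read gene intervals from BED or minimal GFF3, sorted by (chrom, start).

    BED starts are 0-based half-open and converted to 1-based inclusive;
    GFF3 records are kept only when ``type == "gene"``.
    """
    path = Path(path)
    genes: list[GeneInterval] = []
    if format == "bed":
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 fields")
            chrom, start, end = parts[0], parts[1], parts[2]
            name = parts[3] if len(parts) > 3 else f"interval_{ln}"
            try:
                s, e = int(start), int(end)
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from err
            genes.append(GeneInterval(gene_id=name, chrom=chrom, start_bp=s + 1, end_bp=e, source="bed"))
    elif format == "gff3_minimal":
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: GFF3 line needs 9 tab-separated fields")
            chrom, _src, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            if ftype != "gene":
                continue
            attrs = _parse_gff3_attributes(parts[8])
            gid = attrs.get("ID", f"gene_{ln}")
            try:
                s, e = int(start), int(end)
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from err
            genes.append(GeneInterval(gene_id=gid, chrom=chrom, start_bp=s, end_bp=e, source="gff3"))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    genes.sort(key=lambda g: ((0, int(g.chrom)) if g.chrom.isdigit() else (1, g.chrom), g.start_bp))
    return genes


def overlap_genes(
    regions: list[QTLRegion], genes: list[GeneInterval], flank_bp: int = 0
) -> list[RegionGeneHit]:
    """All (region, gene) pairs whose closed 1-based intervals intersect.

    overlap_bp is the inclusive intersection length; ``flank_bp`` extends
    each region symmetrically before testing (0 = window bounds only).
    """
    hits: list[RegionGeneHit] = []
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom.setdefault(str(g.chrom), []).append(g)
    for region in regions:
        lo = region.start_bp - flank_bp
        hi = region.end_bp + flank_bp
        for g in by_chrom.get(str(region.chrom), []):
            ov = min(hi, g.end_bp) - max(lo, g.start_bp) + 1
            if ov >= 1:
                hits.append(RegionGeneHit(region=region, gene_id=g.gene_id, overlap_bp=int(ov)))
    return hits


def hits_to_frame(hits: list[RegionGeneHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.region.chrom, h.region.start_bp, h.region.end_bp, h.region.max_pct, h.gene_id, h.overlap_bp)
            for h in hits
        ],
        columns=["chrom", "region_start_bp", "region_end_bp", "region_max_pct", "gene_id", "overlap_bp"],
    )
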