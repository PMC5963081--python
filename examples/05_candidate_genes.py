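"""Positional candidate genes: overlap QTL regions with gene intervals.

Regions come from the windowed GWAS; genes from a BED (0-based half-open,
converted on read) or minimal GFF3 annotation.  A gene is a hit when the
closed 1-based intervals share at least one base pair.
"""

from pathlib import Path
import tempfile

import gblupgwas as gg
from gblupgwas.annotate import hits_to_frame
from gblupgwas.gwas import QTLRegion

regions = [
    QTLRegion(chrom="3", start_bp=107_748_212, end_bp=108_088_562, max_pct=0.67,
              contributing_windows=[]),
    QTLRegion(chrom="15", start_bp=52_854_077, end_bp=53_676_145, max_pct=0.39,
              contributing_windows=[]),
]

bed = Path(tempfile.mkdtemp()) / "genes.bed"
bed.write_text(
    "3\t107800000\t107900000\tTPH2_like\n"
    "3\t108000000\t108200000\tTRHDE_like\n"
    "15\t53000000\t53100000\tDGAT2_like\n"
    "15\t60000000\t60100000\tELSEWHERE\n"
)
genes = gg.read_annotation(bed, format="bed")
hits = gg.overlap_genes(regions, genes)

print(hits_to_frame(hits).to_string(index=False))
print("\nEach row is a gene whose interval intersects a suprathreshold QTL "
      "region; overlap_bp is the inclusive intersection length.  ELSEWHERE "
      "does not appear because it lies outside every region.")
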