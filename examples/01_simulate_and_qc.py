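"""Simulate a sheep-like study population and apply SNP quality control.

Builds 216 genotyped rams (full-sib, half-sib and unrelated individuals in
14 contemporary groups) with a 2,000-SNP panel, then filters SNPs on sex
chromosomes, monomorphism, minor allele frequency < 0.05, call rate < 0.90
and Hardy-Weinberg heterozygosity deviation > 0.15.
"""

import gblupgwas as gg

cfg = gg.study_config(n_snps=2000, seed=11)
genotypes = gg.simulate_genotypes(cfg)
phenotypes, truth = gg.simulate_phenotypes(genotypes, cfg)

print(f"simulated {genotypes.n_individuals} individuals x {genotypes.n_snps} SNPs "
      f"on {genotypes.snp_map['chrom'].nunique()} chromosomes")
print(f"traits: {list(truth.realized_h2)} with realized h2 "
      f"{ {k: round(v, 2) for k, v in truth.realized_h2.items()} }")

retained, report = gg.apply_qc(genotypes)
print()
print(report.summary())
print()
print("Each removal is attributed to the first violated filter in the order "
      "sex-chromosome, monomorphic, MAF, call rate, HWE deviation; SNPs "
      "sitting exactly on a threshold are kept.")
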