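"""Windowed GWAS: backsolve SNP effects from GEBV and attribute additive
genetic variance to 10-SNP sliding windows.

a_hat = W'(WW')^+ u_hat (unweighted, D = I), then each window of 10
adjacent SNPs gets pct = 100 * Var(sum_j W_j a_hat_j) / sigma2_u.  Windows
at or above 0.30% are merged into candidate QTL regions.  The panel here
carries chip-like LD (ld_decay=0.95) so that windows can concentrate
variance; under linkage equilibrium with many more markers than animals the
decomposition is flat by construction.
"""

import numpy as np

import gblupgwas as gg

cfg = gg.study_config(n_snps=5000, ld_decay=0.95, seed=41)
genotypes = gg.simulate_genotypes(cfg)
phenotypes, truth = gg.simulate_phenotypes(genotypes, cfg)
retained, _ = gg.apply_qc(genotypes)
grm, centered = gg.grm_from_genotypes(retained)

vc, gebv = gg.fit_univariate(gg.make_model_data(phenotypes, grm, "IMF"))
u_hat = gebv.u_hat["IMF"].to_numpy()
effects = gg.backsolve_snp_effects(centered, u_hat)
ident = np.linalg.norm(centered.M @ effects.a_hat - u_hat) / np.linalg.norm(u_hat)
print(f"backsolve projection identity |Wa - u|/|u| = {ident:.1e} (exact by construction)")

windows = gg.window_variances(centered, effects, vc.sigma2_u, window_size=10, mode="sliding")
print(f"{len(windows)} sliding windows; top window explains "
      f"{windows['pct'].max():.3f}% of additive genetic variance")

regions = gg.select_regions(windows, threshold_pct=0.30)
print(f"regions >= 0.30%: {len(regions)}")
for r in regions[:5]:
    print(f"  chr{r.chrom}:{r.start_bp}-{r.end_bp}  length {r.length_bp:,} bp  "
          f"max {r.max_pct:.2f}%")
print("\nGEBV shrinkage attenuates window shares relative to the true "
      "architecture; rerun with truth.true_breeding_values as input to see "
      "the unattenuated decomposition.")
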