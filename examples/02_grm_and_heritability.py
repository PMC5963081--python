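"""Build the VanRaden genomic relationship matrix and estimate a genomic
heritability by AI-REML.

G = MM'/(2*sum p(1-p)) with M the column-centered dosages; its off-diagonal
mean is ~ -1/(n-1) when frequencies come from the analyzed sample, full-sib
pairs sit near 0.5 and unrelated pairs near 0.  The univariate GBLUP model
y = Xb + Zu + e with u ~ N(0, G*sigma2_u) is fitted by restricted maximum
likelihood with average-information updates.
"""

import numpy as np

import gblupgwas as gg

cfg = gg.study_config(n_snps=3000, seed=21)
genotypes = gg.simulate_genotypes(cfg)
phenotypes, truth = gg.simulate_phenotypes(genotypes, cfg)
retained, _ = gg.apply_qc(genotypes)
grm, centered = gg.grm_from_genotypes(retained)

off = grm.matrix[~np.eye(grm.matrix.shape[0], dtype=bool)]
print(f"GRM: mean diagonal {np.diag(grm.matrix).mean():.3f}, "
      f"off-diagonal mean {off.mean():.4f} (~ -1/(n-1) = {-1/215:.4f}), "
      f"max {off.max():.2f} (a full-sib pair)")

data = gg.make_model_data(phenotypes, grm, "IMF")
vc, gebv = gg.fit_univariate(data)
print(f"\nAI-REML converged in {vc.n_iter} iterations")
print(f"sigma2_u = {vc.sigma2_u:.4f} (SE {vc.se['sigma2_u']:.4f}), "
      f"sigma2_e = {vc.sigma2_e:.4f} (SE {vc.se['sigma2_e']:.4f})")
print(f"genomic h2 = {vc.h2['IMF']:.3f} (SE {vc.h2_se['IMF']:.3f}); "
      f"simulated truth {truth.realized_h2['IMF']:.3f}")
print(f"GEBV accuracy vs true breeding values: "
      f"{np.corrcoef(gebv.u_hat['IMF'], truth.true_breeding_values['IMF'])[0, 1]:.2f}")
print("\nAt n=216 the heritability carries a wide confidence interval; the "
      "estimate should bracket the truth within ~1-2 SEs.")
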