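import numpy as np
import pandas as pd
import pytest

import gblupgwas as gg


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study: sib-structured genotypes,
    two correlated traits, QC'd matrix, GRM and centered dosages."""
    cfg = gg.study_config(
        n_individuals=80,
        n_snps=600,
        n_chromosomes=4,
        family_structure=(("full_sib", 24), ("half_sib", 24), ("unrelated", 32)),
        n_groups=6,
        group_size_range=(8, 20),
        seed=42,
        trait_specs=(
            gg.TraitSpec("IMF", mean=3.46, h2_true=0.30, phenotypic_var=0.769**2, n_qtl=100),
            gg.TraitSpec(
                "C18_0", mean=20.29, h2_true=0.30, phenotypic_var=3.342**2, n_qtl=100,
                genetic_corr_with_anchor=0.3, residual_corr_with_anchor=0.2,
            ),
        ),
    )
    genotypes = gg.simulate_genotypes(cfg)
    phenotypes, truth = gg.simulate_phenotypes(genotypes, cfg)
    g_qc, report = gg.apply_qc(genotypes)
    grm, centered = gg.grm_from_genotypes(g_qc)
    return {
        "config": cfg,
        "genotypes": genotypes,
        "phenotypes": phenotypes,
        "truth": truth,
        "g_qc": g_qc,
        "qc_report": report,
        "grm": grm,
        "centered": centered,
    }


@pytest.fixture(scope="session")
def anchor_fit(small_study):
    data = gg.make_model_data(small_study["phenotypes"], small_study["grm"], "IMF")
    vc, gebv = gg.fit_univariate(data)
    return {"data": data, "vc": vc, "gebv": gebv}


def make_genotype_matrix(dosages, chroms=None, bps=None, ids=None):
    """Hand-build a GenotypeMatrix from a dense array (NaN = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chroms = chroms or ["1"] * m
    bps = bps or list(range(1000, 1000 + 1000 * m, 1000))
    ids = ids or [f"i{k}" for k in range(n)]
    snp_map = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(m)], "chrom": chroms, "bp": bps}
    )
    return gg.GenotypeMatrix(dosages=dosages, snp_map=snp_map, individual_ids=ids)
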