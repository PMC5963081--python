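import numpy as np
import pandas as pd
import pytest

import gblupgwas as gg
from gblupgwas.grm import CenteredGenotypes


def _centered_from_random(n, m, seed, n_chrom=2):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    M = dos - dos.mean(axis=0)
    per = m // n_chrom
    chroms = [str(c + 1) for c in range(n_chrom) for _ in range(per)]
    chroms += [str(n_chrom)] * (m - len(chroms))
    snp_map = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": chroms,
        "bp": np.concatenate([np.arange(1, 1 + (np.array(chroms) == c).sum()) * 1000
                              for c in dict.fromkeys(chroms)]),
    })
    return CenteredGenotypes(M=M, freqs=p, snp_map=snp_map,
                             individual_ids=[f"i{k}" for k in range(n)])


# ---------------------------------------------------------------------------
# backsolve


def test_backsolve_projection_identity():
    """With D = I and u_hat in the column space of M (always true for GBLUP
    breeding values), M a_hat reproduces u_hat to machine precision."""
    cent = _centered_from_random(50, 200, seed=1)
    rng = np.random.default_rng(2)
    u = cent.M @ rng.normal(size=200)  # in the column space by construction
    eff = gg.backsolve_snp_effects(cent, u)
    assert np.linalg.norm(cent.M @ eff.a_hat - u) / np.linalg.norm(u) < 1e-6


def test_backsolve_single_snp_scalar_solution():
    cent = _centered_from_random(30, 1, seed=3)
    alpha = 2.5
    u = alpha * cent.M[:, 0]
    eff = gg.backsolve_snp_effects(cent, u)
    assert eff.a_hat[0] == pytest.approx(alpha, rel=1e-10)


def test_backsolve_permutation_equivariance():
    cent = _centered_from_random(40, 60, seed=4)
    rng = np.random.default_rng(5)
    u = cent.M @ rng.normal(size=60)
    a = gg.backsolve_snp_effects(cent, u).a_hat
    perm = rng.permutation(60)
    cent_p = CenteredGenotypes(
        M=cent.M[:, perm], freqs=cent.freqs[perm],
        snp_map=cent.snp_map.iloc[perm].reset_index(drop=True),
        individual_ids=cent.individual_ids,
    )
    a_p = gg.backsolve_snp_effects(cent_p, u).a_hat
    np.testing.assert_allclose(a_p, a[perm], atol=1e-10)


def test_backsolve_scale_equivariance():
    cent = _centered_from_random(40, 60, seed=6)
    rng = np.random.default_rng(7)
    u = cent.M @ rng.normal(size=60)
    a = gg.backsolve_snp_effects(cent, u).a_hat
    a_scaled = gg.backsolve_snp_effects(cent, 3.0 * u).a_hat
    np.testing.assert_allclose(a_scaled, 3.0 * a, atol=1e-10)


def test_backsolve_dimension_and_weight_validation():
    cent = _centered_from_random(10, 5, seed=8)
    with pytest.raises(ValueError, match="length"):
        gg.backsolve_snp_effects(cent, np.zeros(7))
    with pytest.raises(ValueError, match="positive"):
        gg.backsolve_snp_effects(cent, np.zeros(10), weights=np.array([1, 1, -1, 1, 1.0]))


# ---------------------------------------------------------------------------
# window variances


def test_zero_effects_give_zero_windows():
    cent = _centered_from_random(20, 40, seed=9)
    eff = gg.SNPEffectSet(a_hat=np.zeros(40), snp_map=cent.snp_map)
    w = gg.window_variances(cent, eff, sigma2_u=1.0)
    assert (w["pct"] == 0).all()


def test_sliding_window_count_per_chromosome():
    cent = _centered_from_random(20, 60, seed=10, n_chrom=2)  # 30 SNPs per chrom
    eff = gg.SNPEffectSet(a_hat=np.ones(60), snp_map=cent.snp_map)
    w = gg.window_variances(cent, eff, sigma2_u=1.0, mode="sliding")
    counts = w.groupby("chrom").size()
    assert (counts == 30 - 10 + 1).all()


def test_window_pct_invariant_to_consistent_rescaling():
    """u_hat -> c*u_hat with sigma2_u -> c^2*sigma2_u leaves every window
    percentage unchanged."""
    cent = _centered_from_random(30, 50, seed=11)
    rng = np.random.default_rng(12)
    u = cent.M @ rng.normal(size=50)
    a1 = gg.backsolve_snp_effects(cent, u)
    a2 = gg.backsolve_snp_effects(cent, 4.0 * u)
    w1 = gg.window_variances(cent, a1, sigma2_u=2.0)
    w2 = gg.window_variances(cent, a2, sigma2_u=2.0 * 16.0)
    np.testing.assert_allclose(w1["pct"], w2["pct"], rtol=1e-10)


def test_blocked_windows_sum_near_total_under_le():
    """In linkage equilibrium, blocked window variances are nearly additive:
    their sum is within 10% (relative) of the total 100*Var(M a)/sigma2_u."""
    cent = _centered_from_random(400, 1000, seed=13, n_chrom=4)
    rng = np.random.default_rng(14)
    a = rng.normal(size=1000) * 0.01
    eff = gg.SNPEffectSet(a_hat=a, snp_map=cent.snp_map)
    s2u = float(np.var(cent.M @ a, ddof=1))
    w = gg.window_variances(cent, eff, sigma2_u=s2u, mode="blocked")
    total = 100.0
    assert abs(w["pct"].sum() - total) / total < 0.10


def test_window_argument_validation():
    cent = _centered_from_random(10, 20, seed=15)
    eff = gg.SNPEffectSet(a_hat=np.zeros(20), snp_map=cent.snp_map)
    with pytest.raises(ValueError):
        gg.window_variances(cent, eff, sigma2_u=0.0)
    with pytest.raises(ValueError):
        gg.window_variances(cent, eff, sigma2_u=1.0, window_size=0)
    with pytest.raises(ValueError):
        gg.window_variances(cent, eff, sigma2_u=1.0, mode="hopping")


# ---------------------------------------------------------------------------
# region selection and window length


def _wdf(rows):
    return pd.DataFrame(rows, columns=["chrom", "start_snp_index", "start_bp", "end_bp", "n_snps", "pct"])


def test_threshold_is_inclusive_at_030():
    w = _wdf([("1", 0, 100, 200, 10, 0.29), ("1", 20, 500, 600, 10, 0.31)])
    regions = gg.select_regions(w, 0.30)
    assert len(regions) == 1
    assert regions[0].start_bp == 500
    # a window sitting exactly on the threshold is kept
    w2 = _wdf([("1", 0, 100, 200, 10, 0.30)])
    assert len(gg.select_regions(w2, 0.30)) == 1


def test_no_suprathreshold_windows_gives_empty_list():
    w = _wdf([("1", 0, 100, 200, 10, 0.05)])
    assert gg.select_regions(w, 0.30) == []


def test_overlapping_windows_merge_with_max_pct():
    w = _wdf([("1", 0, 100, 200, 10, 0.35), ("1", 5, 150, 300, 10, 0.55)])
    regions = gg.select_regions(w, 0.30)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start_bp, r.end_bp, r.max_pct) == (100, 300, 0.55)


def test_regions_on_different_chromosomes_not_merged():
    w = _wdf([("1", 0, 100, 200, 10, 0.35), ("2", 0, 100, 200, 10, 0.35)])
    assert len(gg.select_regions(w, 0.30)) == 2


def test_window_length_convention():
    assert gg.window_length(78397685, 78915234) == 517549
    assert gg.window_length(5, 5) == 0
    with pytest.raises(ValueError, match="reversed"):
        gg.window_length(10, 5)


def test_gblup_snp_blup_consistency(small_study, anchor_fit):
    """GEBV from the mixed-model equations equal M a_hat after backsolving
    (the GBLUP <-> SNP-BLUP equivalence)."""
    cent = small_study["centered"]
    u = anchor_fit["gebv"].u_hat["IMF"].to_numpy()
    eff = gg.backsolve_snp_effects(cent, u)
    assert np.linalg.norm(cent.M @ eff.a_hat - u) / np.linalg.norm(u) < 1e-6
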