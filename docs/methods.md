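# Methods

## Scope

`gblupgwas` re-implements, as a tested library, the genomic analysis used in
small-livestock fatty-acid studies: SNP quality control, a realized genomic
relationship matrix (VanRaden method 1), univariate and anchor-trait
bivariate GBLUP fitted by AI-REML, genomic heritabilities with standard
errors, SNP-effect backsolving from genomic breeding values, decomposition
of additive genetic variance into windows of 10 adjacent SNPs,
suprathreshold QTL-region selection, and positional candidate-gene overlap.
Because studies of this kind frequently deposit no genotype data, the
package ships a synthetic-data generator that emulates the study population
and provides ground truth for every downstream stage.

## Models

### Mixed model and REML

Per trait, `y = Xb + Zu + e` with `u ~ N(0, G sigma2_u)` and
`e ~ N(0, I sigma2_e)`; `X` holds an intercept plus drop-first contemporary-
group contrasts (reference = first group by label sort), `Z` maps
observations to rows of `G`.  The restricted log-likelihood is evaluated
densely, `-1/2 [log|V| + log|X'V^-1X| + y'Py]` up to a constant, which at a
few hundred individuals is both the simplest and an entirely adequate
strategy (one Cholesky factorization of an n x n or 2n x 2n matrix per
iteration).

Estimation is average-information REML:

* score `dl/dt_k = -1/2 [tr(P dV_k) - y'P dV_k P y]`, average information
  `AI_kl = 1/2 y'P dV_k P dV_l P y`;
* an AI step is accepted only if it stays in the parameter space and does
  not decrease the likelihood; otherwise the step is halved (6 times), then
  an active-set retry pins components the step drives below zero at the
  floor and re-solves for the remainder, then Harville's monotone EM update
  `t_k <- t_k + (2 t_k^2 / q_k) dl/dt_k` is the final fallback.  Without
  the active-set retry, boundary optima (sigma2_u -> 0) are approached by a
  geometrically slowing EM crawl that exhausts the iteration budget;
* convergence at relative parameter change < 1e-8 or gradient norm < 1e-6,
  with KKT handling at the boundary (a component clamped at the floor,
  1e-10 * Var(y), whose gradient points further down counts as converged);
* `algorithm="em"` runs pure EM, whose likelihood trace is provably
  non-decreasing (asserted by a test);
* standard errors from the inverse AI matrix at the optimum; the SE of
  h2 = sigma2_u/(sigma2_u + sigma2_e) and of the genetic correlation by the
  delta method.  The SE method of the original study is unknown, so SEs are
  reported but never compared against published ones.

### Anchored bivariate model

Two traits stack with `u ~ N(0, G (x) H)` and `e ~ N(0, I (x) R)` (2x2
genetic and residual covariance matrices; residual covariance applies only
to observations on the same individual, so traits observed on different
subsets are handled).  The anchor variant holds trait 1's `sigma2_u` and
`sigma2_e` fixed at externally supplied values — the device used to protect
variance components against selection bias when the sample may have been
selected on a fatness proxy — and estimates `(H12, H22, R12, R22)` by the
same AI scheme under the PSD constraints `H12^2 <= H11 H22`,
`R12^2 <= R11 R22`.  Step halving down to a diagonally-scaled gradient
keeps the trace non-decreasing; a point from which no feasible improving
step exists is reported as a constrained stationary point.  A clean
monotone EM for this partially-fixed parameterization has no simple closed
form, which is why the pure-EM mode exists only for the univariate model.

### GRM

VanRaden method 1: `G = MM'/k`, `M = dosages - 2p` per SNP,
`k = 2 sum p(1-p)`.  Frequencies are always re-estimated from the analyzed
sample (there is no external reference population), hence column means of
`M` are zero, every row of `G` sums to zero and `1'G1 = 0` — both asserted.
Missing dosages are imputed to the SNP mean (exactly 0 after centering).
Because n can exceed the marker rank, `G` is blended as
`G* = (1-d)G + dI` with `d = 0.01` by default (switchable); all REML fits
use the blended matrix.

### Backsolve and windows

SNP effects from breeding values: `a_hat = D W' (W D W')^+ u_hat` with
`W = M` (the same centered matrix as the GRM — this makes
`W a_hat = u_hat` an exact identity whenever `u_hat` lies in the column
space of `W`, which GBLUP breeding values do by construction) and `D = I`
unless per-SNP weights are supplied.  The pseudoinverse is a symmetric
eigendecomposition with relative eigenvalue cutoff 1e-10, safe for the
rank-deficient `WW'` that arises when n < m.

Window share of additive variance:
`pct = 100 * Var(sum_{j in window} W_j a_hat_j) / sigma2_u`, where `Var` is
the sample variance across individuals (n-1 denominator) and `sigma2_u` is
the REML additive variance of the trait (not `Var(u_hat)`).  Windows hold
10 adjacent SNPs, never span chromosomes, and slide by 1 SNP by default
(blocked mode is available); sliding is the default because published
window tables show near-identical but shifted windows across traits, which
only a stride-1 scheme produces.  Windows with `pct >= 0.30` (threshold
inclusive) merge into QTL regions when their base-pair intervals overlap or
touch; a region carries the maximum window percentage.  Reported window
length is `end_bp - start_bp`.

### Annotation

Gene intervals from BED (0-based half-open, converted on read) or minimal
GFF3 (`type == gene`, `ID` attribute).  Internally all coordinates are
1-based inclusive; a gene is a positional candidate when the closed
intervals share >= 1 bp (any overlap, not containment — the stricter
convention is recoverable via `overlap_bp`).  No flanking by default;
`flank_bp` extends regions symmetrically.

## Quality control

Filters in a fixed order — sex chromosomes, monomorphic, MAF < 0.05, call
rate < 0.90, |observed - expected heterozygote frequency| > 0.15 — with
each removal attributed to the first violated filter, so reports are
reproducible when a SNP violates several.  All thresholds are strict
(boundary kept), with a 1e-9 absolute guard so counts landing exactly on a
threshold (e.g. a het deviation of 26/40 - 1/2 = 0.15) are not removed by
binary-representation noise.  The heterozygosity screen is an absolute
difference; whether the original filter was absolute-valued is unstated, so
the choice is flagged in the report header.  Individual-level call-rate
filtering exists but is disabled by default (the emulated study removed no
animals).

## Synthetic data

The generator emulates the study population: 216 genotyped males, 14
contemporary groups of 6-20, 26 autosomes, allele frequencies uniform on
(0.01, 0.5), and a relationship mixture of full-sib families, half-sib
families and unrelated individuals.  Sib families default to size 8; with
96 full-sib, 72 half-sib and 48 unrelated individuals the off-diagonal of
`G` has mean ~ -1/(n-1) = -0.005 and SD ~ 0.065 under linkage equilibrium,
matching the reported relationship summary (the reported maximum of 0.97
would require a near-duplicate pair and is not emulated; full-sib pairs put
the maximum near 0.6-0.8).

Founder haplotypes are Bernoulli(p) per SNP; optional LD comes from a
first-order Markov copying walk along each chromosome (`ld_decay` = copy
probability, 0 = linkage equilibrium, the default).  Offspring receive one
whole-chromosome haplotype per parent (no intra-chromosome recombination —
adequate for relationship structure over 26 autosomes, and recombination
maps are out of scope).  Phenotypes are `mean + group + u + e`: group
effects N(0, 0.25 * Vp) (group SD = half the trait SD — the emulated study
gives group structure but not its variance), `u` built from `n_qtl` marker
effects on the centered dosages and rescaled so the sample genetic variance
equals `h2 * Vp` exactly (exact control makes recovery tests sharp), and
correlated traits formed by mixing the anchor's standardized breeding value
and residual with independent own components.  `n_qtl` defaults to 300 per
trait — polygenic, with true top-QTL shares of a few percent.  The truth
record carries breeding values, QTL indices/effects and realized h2.

What the generator does **not** emulate: ancestral LD blocks, site
frequency spectra of real chips, genotyping error, selection, or
recombination within chromosomes.  Consequences are discussed under
Limitations.

## Problem sizes and test design

Tests run at sizes where the checked property is informative and the suite
stays fast: likelihood-oracle equivalence on 10 fixtures with n <= 25
against a coarse-to-fine 2-D grid search of the restricted likelihood
(final resolution 1e-3 on unit-variance data); univariate h2 recovery at
n=500, m=2000 over 20 replicates (study-like sib mixture; per-replicate SD
of h2-hat is ~0.10, so the mean is the meaningful quantity); anchored
bivariate rg recovery at the same scale; null calibration (h2=0, rg=0)
under conditions where the estimator's sampling spread makes the check
discriminating — the null spread of h2-hat scales with the realized
relationship variation, which between nominally unrelated individuals
shrinks like 1/m, so the h2=0 check uses a modest 80-SNP panel plus sib
families rather than a dense panel on which no correct REML could
concentrate 90% of its null mass below 0.05.

The window-localization check plants one QTL carrying 5% of the additive
variance on a polygenic background (m=1000, linkage equilibrium) and feeds
the *known* genetic values through backsolve + windows at n=1000; the
maximum window contains the QTL in >= 90% of replicates.  Feeding known
values isolates localization from GEBV estimation error, which at small n
dominates (see Limitations).

## Limitations

* **Window attenuation at m >> n.**  The minimum-norm backsolve spreads
  `u_hat` over all markers; when the effective marker dimension is much
  larger than n, no 10-SNP window can concentrate variance, and GEBV-level
  window shares fall orders of magnitude below truth-level shares.
  Empirically, truth-level windows reach the 0.3-1% range only when the
  effective dimension (segments of the LD walk) is comparable to or below
  n.  The end-to-end demonstration in `scripts/acceptance.py` therefore
  runs 216 individuals against a 5,000-SNP panel with `ld_decay=0.95`
  (effective dimension ~130) and reports both the GEBV-level and the
  truth-level decomposition.  Published analyses at 42k markers owe their
  suprathreshold windows to real-chip LD and family haplotype structure
  that a stationary copying model cannot reproduce; region *counts* from
  such analyses are emulated in structure, not in number.
* **Heritability precision at n=216** is intrinsically low (SE ~ 0.1 even
  with strong families); single-run estimates scatter widely around the
  truth and only replicate means are tight.  Published SEs of ~0.04 at this
  sample size are not reproduced by the AI information matrix under any
  population structure the generator can build.
* **Genetic correlations at n=216** are extremely noisy (SD ~ 0.3+); the
  anchored model constrains but cannot rescue them.
* The LD model preserves adjacent-marker correlation but changes marginal
  frequencies slightly when frequencies vary along the chromosome, and its
  correlation decays geometrically — unlike real chips.
* Boundary estimates (h2 = 0) are clamped at a floor rather than profiled;
  SEs at the boundary are not trustworthy (standard REML caveat).
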