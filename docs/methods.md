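# Methods

This note documents the statistical models implemented in `medmr`, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Two-sample MR model

All estimators work on summary statistics from *non-overlapping* cohorts:
per-variant marginal effects β̂x (exposure), β̂m (mediator), β̂ʏ (outcome,
log-OR scale), each with standard errors. A variant j qualifies as an
instrument when its exposure association passes the significance threshold,
survives LD clumping, and has F_j = (β̂x_j/SE_j)² ≥ 10.

**Thresholds.** Lipid species are polygenic with mostly sub-genome-wide
hits, so their instrument threshold is relaxed to p < 1 × 10⁻⁵; proteins
use genome-wide 5 × 10⁻⁸ (top cis-pQTLs are strong, and stricter selection
limits pleiotropy). Clumping is greedy: the smallest-p unretired variant
retires all same-chromosome variants within 10,000 kb (inclusive) with
r² ≥ 0.001 against it; ties in p break by smaller position then id, making
output order-invariant. The F boundary keeps F = 10 exactly (variants with
F < 10 are excluded).

**Harmonization.** Variants are matched by id only. Swapped outcome alleles
negate β̂ʏ and mirror the EAF. Palindromic (A/T, C/G) single-base variants
are resolvable only through allele frequency: both EAFs must be known and
outside [0.42, 0.58]; frequencies on opposite sides of 0.5 imply a strand
flip. Remaining pairs with |ΔEAF| > 0.2 are dropped as discordant. Indel
alleles are accepted but never treated as palindromic. All drops carry a
status and a logged count.

## Estimators

With Wald ratios r_j = β̂ʏ_j/β̂x_j, first-order SE_j = SEʏ_j/|β̂x_j| and
weights w_j = 1/SE_j²:

- **IVW**: β̂ = Σw_j r_j/Σw_j, fixed SE = (Σw_j)^{-1/2}. The default
  multiplicative-random-effects mode inflates the SE by
  max(1, √(Q/(k−1))), Q = Σw_j(r_j − β̂)² being Cochran's Q (χ²_{k−1}
  under homogeneity). The floor at 1 matches standard two-sample MR
  practice; it makes the random-effects p slightly conservative under
  homogeneity, which is why calibration tests target the fixed mode.
- **MR-Egger**: after orienting β̂x_j ≥ 0 (required for the intercept to
  measure directional pleiotropy), weighted least squares of β̂ʏ on β̂x
  with a free intercept, weights 1/SEʏ², SEs scaled by
  max(1, √(RSS_w/(k−2))); slope and intercept referred to t_{k−2}. The same
  SE floor makes the intercept test conservative rather than exactly
  uniform under the null — deliberate, and asserted as such in the tests.
- **Weighted median**: the ratio at the 0.5 crossing of the cumulative
  normalized weights over the sorted ratios. The crossing form (rather than
  midpoint interpolation) guarantees that a ratio carrying a strict
  majority of weight is returned exactly — the property that justifies the
  estimator's robustness claim; an exact boundary hit averages the two
  neighbours. SE by parametric bootstrap (default 1000 replicates,
  r_j* ~ N(r_j, SE_j), fixed recorded seed).
- **Maximum likelihood**: β̂x_j ~ N(ξ_j, SEx_j²), β̂ʏ_j ~ N(θξ_j, SEʏ_j²)
  independently; profiling out ξ_j gives
  ℓ(θ) = −½ Σ (β̂ʏ_j − θβ̂x_j)²/(SEʏ_j² + θ²SEx_j²), maximized by bounded
  Brent iteration (tol 1e-10, ≤200 iterations, started from the
  SEx→0 closed form); SE from the numerical curvature of ℓ at θ̂.

ORs are exp(β) with CI exp(β ± 1.959964·SE); ln-OR/CI-to-SE conversions use
the same constant.

## SMR and HEIDI

At the protein's top cis-pQTL (smallest p within ±1000 kb of the gene,
p < 5 × 10⁻⁸, ties to the smaller position), b_xy = β̂_GWAS/β̂_QTL and
T_SMR = z²_GWAS z²_QTL/(z²_GWAS + z²_QTL) ~ χ²₁; this is symmetric in the
two z-scores and converges to z²_GWAS as the pQTL strengthens.

HEIDI contrasts d_i = b_xy(i) − b_xy(top) over cis SNPs with
p_QTL < 1.57 × 10⁻³ and 0.05 < r²(i, top) < 0.9 (at most 20 by descending
|z_QTL|; fewer than 3 leaves the test undefined with a recorded reason).
The covariance of d comes from first-order propagation of the LD-induced
covariance of marginal effects (cov ≈ r_ij·SE_i·SE_j per trait, zero across
the independent cohorts). T = Σ d_i²/var(d_i) is referred to a
Satterthwaite scaled χ²: a·χ²_ν with a = Var(T)/(2E T), ν = 2(E T)²/Var(T),
Var(T) = 2‖corr(d)‖²_F. This two-moment approximation is accurate at the
0.01 decision threshold and avoids eigenvalue decompositions; it is
documented as approximate. A protein "passes" the scan when its BH-adjusted
SMR p is < .05 **and** HEIDI does not reject (p ≥ .01).

## Colocalization

Per SNP and trait, the Wakefield log-ABF is ½ln(V/(V+W)) + z²W/(2(V+W))
with V = SE², W the prior effect variance. Prior effect SDs default to 0.15
(quantitative traits, SD units) and 0.2 (binary, log-OR) — the canonical
coloc defaults, since only the configuration priors p1 = p2 = 10⁻⁴,
p12 = 10⁻⁵ are fixed by the study design. Hypothesis sums are accumulated
with log-sum-exp; H3 (distinct variants) is the full product sum minus the
diagonal, computed as ls1 + ls2 + log(1 − exp(ls12 − ls1 − ls2)) with
`expm1` for stability; when one SNP dominates both traits the off-diagonal
mass underflows and H3 is reported as exactly zero — the correct limit. A
single-SNP region gives PPH3 = 0 identically. Variants present in only one
trait are dropped complete-case with a logged count. PPH4 > 0.6 flags
strong colocalization.

## Mediation

Mediated effect = a·b with SE = √(a²SE_b² + b²SE_a²) (first-order/delta,
symmetric in the two legs; sign(a·b) = sign(a)·sign(b) always). Proportion
mediated = 100·a·b/total, signed; its CI uses the independence delta
method, SE_% = |prop|·√((SE_ab/ab)² + (SE_tot/tot)²), chosen because the
study design names error propagation without a formula — the choice is
recorded in the output and configurable. When sign(a·b) ≠ sign(total) or
|prop| > 100 the additive-mediation assumption is violated and the row is
flagged rather than suppressed. Leg estimators default to IVW
(multiplicative random effects); the protein→disease leg may be overridden
(e.g. by SMR's b_xy). Report-time rounding is 3 dp for betas and 2
significant figures for percentages; computation never rounds.

## Synthetic data

`simulate_study` draws **three independent cohorts** (one per trait, so
cross-table errors carry no sample overlap — the two-sample assumption) and
an external LD reference panel (default n = 5000).

- **Genotypes**: exchangeable latent-Gaussian blocks thresholded at the MAF
  quantile, two haplotypes summed to a dosage. The latent correlation is
  calibrated through the tetrachoric map so the *dosage* correlation hits
  the scenario's ρ; MAF is drawn per block (shared within it) because
  heterogeneous frequencies bound the attainable correlation. MAFs are tied
  to the scenario seed, not the cohort draw, so cohorts share allele
  frequencies.
- **Chain**: exposure = causal score + noise (unit variance); mediator =
  a·exposure + its own score + noise (unit variance); outcome ~
  Bernoulli(logistic(α + b·mediator + c′·exposure + own loci)), α solved by
  bisection for the target prevalence (default 0.05, a desk-scale version
  of a case–control disease GWAS).
- **Summary statistics**: per-variant OLS (quantitative) or vectorized
  Newton logistic regression (binary; separated variants dropped and
  logged) — the estimator real cohorts use, preserving LD-induced
  correlation between neighbouring effects. EAF is exactly the dosage
  mean/2.
- **Fast analytic route**: `sample_summary_stats` draws β̂ ~
  MVN(β_true, D R D) with D = diag(1/√(n·var g)) (×1/√(prev(1−prev)) for
  logistic), the large-sample distribution of marginal effects.
  `population_marginal_betas` supplies exact truth under the block model
  (tag marginal = ρ·effect); the empirical panel version differs by
  O(1/√n) LD noise, which matters — using empirical "truth" visibly biases
  replicate coverage. The two routes are cross-checked in the tests.

**Presets** (`scenario_presets()`): `mediation_chain` encodes the published
discovery pathway (a = −0.045, b = −0.062, total = 0.097, hence
c′ = total − ab), 12 exposure and 12 mediator loci of 0.18 SD/allele in
distinct blocks — per-locus variance ~1%, a realistic polygenic
architecture that yields ~12 instruments at p < 10⁻⁵; `null` keeps the
genetics but cuts the chain; `shared_causal` has one 0.35 SD cis-pQTL whose
protein drives disease (log-OR 0.5/SD — large, as expected of a
colocalizing drug-target locus); `linkage` puts the protein's causal
variant and a distinct disease locus (log-OR −0.3, a strong GWAS hit, with
the opposite sign) in the same LD block (dosage r² ≈ 0.36). Defaults:
n = 20,000 individuals, 500 variants in 10-variant blocks, ρ = 0.6,
MAF ∈ (0.1, 0.5).

**What a green test establishes.** The generator emulates the *statistical
shape* of GWAS summary data: marginal effects with LD-correlated noise, SEs
scaling with N and allele frequency, a directed causal chain. It does not
emulate realistic human LD maps, imputation error, ancestry structure,
sample overlap or selection bias, so passing recovery tests demonstrate
estimator correctness under the stated model, not robustness to those
artefacts. At the published effect sizes and desk-scale n, single-study
mediation point estimates are noise-dominated; the suites therefore assert
replicate CI coverage and calibration rates, not single-draw accuracy.

## Numerical choices and degenerate inputs

- p-values from |z| use the normal survival function ×2; Egger uses
  t_{k−2}; SMR/HEIDI use χ² tails. Reported p-values are clipped to
  ≥ 1e-300 when generated synthetically.
- Stated p-values are preserved on read even when inconsistent with β/SE
  (a warning is logged) — provenance over recomputation.
- Zero-variance dosage columns, se ≤ 0, identical alleles, β_exposure = 0
  instruments, and empty variant intersections are typed errors naming the
  offending variant; an exposure with no surviving instruments is a typed
  *result* so scans continue.
- Weighted-median bootstrap, simulation seeds and config hashes are echoed
  into every report header; pipeline outputs are bit-reproducible given the
  seed.

## Known limitations

- HEIDI's Satterthwaite tail and first-order ratio covariance are
  approximations; very weak top-pQTLs (|z| near the eligibility bound) make
  the d-ratios heavy-tailed and the test anticonservative in principle —
  mitigated by the z-eligibility threshold, not eliminated.
- The analytic sampler assumes unit-variance traits and modest per-variant
  R²; it is exact only in the large-n limit.
- No Steiger filtering, proxy-SNP lookup, multivariable MR, MR-PRESSO,
  SuSiE colocalization, or natural-effect decompositions; single causal
  variant per trait per region is assumed by the colocalization model.
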