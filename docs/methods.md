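# Methods

## The testing problem

In a univariate GWAS a phenotype is regressed on the allele count of a SNP,
yielding one p-value. With `m` phenotypes measured on the same subjects one
obtains `m` correlated univariate p-values per SNP, and a combination test
turns them into a single p-value for the multivariate null hypothesis that
the SNP is associated with none of the phenotypes. This package implements
the four weighted-selection combination tests — each weights the `m`
p-values, selects the smallest weighted value, and reports it — together
with a Monte-Carlo engine for studying their Type I error under the null
with correlated phenotypes.

Write `p_(1) ≤ … ≤ p_(m)` for the ascendingly sorted p-values.

* **minP_Bonf** — `min(1, m · p_(1))` (Bonferroni).
* **minP_NS** — replaces `m` by the effective number of phenotypes
  `M_eff` obtained from the eigenvalues `λ_1 … λ_m` of the phenotypic
  correlation matrix:

      M_eff = 1 + (m − 1) · (1 − Var(λ) / m),

  with the sample variance (denominator `m − 1`). Since `M_eff ≤ m`,
  minP_NS is never stricter than minP_Bonf. Two correction styles are
  available: multiplicative `min(1, M_eff · p_(1))` (default) and Šidák
  `1 − (1 − p_(1))^M_eff`. At `α = 0.05` their rejection thresholds differ
  by less than 3·10⁻⁴, so the simulated rates barely distinguish them;
  the multiplicative style matched the reference rates marginally better
  in our runs and is the literal "smallest weighted p-value" form.
* **Simes** — `min_j (m / j) · p_(j)`.
* **TATES** — the extended Simes test: `min_j (m_e / m_ej) · p_(j)` with

      m_ej = j − Σ_{i=1..j} I(λ_i > 1)(λ_i − 1),

  where the `λ_i` are eigenvalues of the leading `j × j` submatrix of the
  correlation matrix **of the p-values**, rows/columns reordered to follow
  the ascending sort of the p-values, and `m_e = m_em`. All weights are
  ≥ 1, the largest sorted p-value always gets weight exactly 1, and with an
  identity correlation matrix TATES reduces exactly to Simes.

Weighted values exceeding 1 are truncated to 1 before selection (reachable
only when every weighted value exceeds 1). Degenerate inputs `p = 0` and
`p = 1` are legal and propagate through the weighting unchanged.

## The p-value correlation map

TATES needs the correlation matrix of the `m` p-values, which is not
observed. It is approximated from the phenotypic correlations `r` through a
pluggable entrywise map (`register_pvalue_map`). The default,
`"tates_polynomial"`, is the sixth-order polynomial used by the GATES/TATES
software,

    r_p ≈ 0.2982 r⁶ − 0.0127 r⁵ + 0.0588 r⁴ + 0.0099 r³ + 0.6281 r² − 0.0009 r,

applied to `|r|` (two-sided p-values are insensitive to the sign of the
association, so the p-value correlation is even in `r`), with `|r| = 1`
mapped to exactly 1. An `"identity"` map (use the phenotypic correlations
directly) is also provided. The choice matters: the polynomial shrinks
moderate correlations substantially (0.9 → 0.70), which raises the TATES
weights and is what makes the test slightly conservative at large `m` and
`r`; with the identity map the simulated Type I error at `m = 16, r = 0.9`
rises from ≈ 0.037 to ≈ 0.068. The polynomial default reproduces the
reference simulation study; the identity map is retained for sensitivity
analysis.

## Univariate association tests

Each phenotype is regressed on the allele count by OLS with an intercept
and no covariates; the slope's two-sided p-value uses the t distribution
with `N − 2` degrees of freedom. The implementation computes
`t = r √((N−2)/(1−r²))` from the genotype–phenotype sample correlation,
which is algebraically identical to the OLS slope test and vectorizes over
replicates and phenotypes. A monomorphic (constant) genotype vector admits
no slope test and raises an error. Under multivariate-normal phenotypes the
t-test is exact, so the univariate null p-values are exactly Uniform(0, 1)
at any `N ≥ 3`.

## The simulation design

The null-simulation study follows a 20-cell grid: `m ∈ {2, 4, 8, 16}`
phenotypes crossed with compound-symmetric correlations
`r ∈ {0.1, 0.3, 0.5, 0.7, 0.9}` (a single parallel factor structure),
`N = 2000` subjects per replicate, one unassociated diallelic variant with
MAF = 0.5, and `α = 0.05`. Two additional high-correlation replication
scenarios are built in: `m = 2` with `r = 0.9343`, and `m = 3` with
`r₁₂ = 0.81, r₁₃ = 0.95, r₂₃ = 0.78`.

Generator choices:

* **Genotypes**: allele counts drawn i.i.d. Binomial(2, MAF) — exactly the
  Hardy–Weinberg genotype frequencies `((1−q)², 2q(1−q), q²)`. The engine
  redraws the (practically never occurring at N = 2000) monomorphic rows.
* **Phenotypes**: i.i.d. rows from a zero-mean multivariate normal with
  unit variances and the scenario's correlation matrix, via a Cholesky (or,
  for singular PSD matrices, eigenvalue) factor. The normal model is the
  standard choice in this literature and makes the univariate tests exact.
* **Independence**: genotypes and phenotypes are drawn independently, so
  the global null holds by construction.
* **Streams**: each scenario seed spawns one substream per fixed-size batch
  of 500 replicates (genotypes drawn before phenotypes within a batch, and
  every batch drawn at full size even when partially used). Results are
  therefore bit-reproducible for a given seed, and increasing `nsim`
  extends a run without rewriting earlier replicates.

The combination tests are applied with the scenario's **true** generating
correlation matrix (deterministic and fast); a sensitivity mode
(`use_sample_corr=True`) instead uses each replicate's sample correlation
matrix. For exchangeable (compound-symmetric) matrices every principal
submatrix is compound symmetric with the same `r`, so the TATES weight
vector is permutation-invariant and computed once per scenario; for general
matrices weights are memoized per observed sort permutation.

Rejections are counted with the strict inequality `combined_p < α` (ties at
`α` have probability zero under the continuous model). The 95% CI for an
unbiased empirical rate uses the binomial normal approximation
`α ± 1.96 √(α(1−α)/nsim)`; grid cells are flagged against the reference
intervals at `nsim = 100,000` (narrow) and `nsim = 10,000` (wide), and the
CLI additionally reports whether a rate falls outside the CI at the actual
`nsim` of the run.

## Problem sizes

The packaged study runs the 20-scenario grid at 10,000 replicates per
scenario (the reference study used 100,000) and the two replication
scenarios at 20,000 replicates. At these sizes the per-rate Monte-Carlo
standard error is `√(0.05·0.95/10⁴) ≈ 0.0022`, the standard error of a
20-cell mean is ≈ 0.0005, and the full grid completes in a few minutes on
one CPU. Rates at several `α` levels (e.g. 0.05 and 0.01) are recounted
from a single simulated grid by keeping the per-replicate combined p-values
(`keep_pvalues=True` / `rejection_rates`).

## Null p-value distributions

`pvalue_distribution` bins the combined null p-values (20 equal-width bins
by default) and computes each method's Kolmogorov–Smirnov distance from
Uniform(0, 1). The univariate p-values a combination test consumes are
uniform under the null, but the weighted-selection combined p-value is not:
constant-weight selection (minP_Bonf, minP_NS) produces a right-skewed
distribution (median > 0.5) in every scenario, while for the sorted-weight
tests (Simes, TATES) the departure from uniformity grows with `m` and `r`
— Simes is exactly uniform under independence (Simes' theorem), and at
`m = 2` with very high `r` TATES degenerates toward the raw minimum
p-value and is again near-uniform. At large `m` and `r` the bulk of the
TATES p-values sits in the top bins. Non-uniformity of a selection-based
combined p-value is expected and does not by itself invalidate the test;
the operative question is the rejection rate at the chosen `α`.

## What the synthetic data do and do not show

The generator emulates exactly the idealized conditions of the study
design: normal homoscedastic phenotypes with an exchangeable (or fully
specified) correlation structure, a single variant in Hardy–Weinberg
equilibrium, no missingness, no covariates, and a true null. Passing tests
therefore demonstrate the distributional behaviour of the combination
tests under those conditions; they say nothing about robustness to
non-normal phenotypes, case–control outcomes, covariate adjustment,
population structure, missing data, or estimated (rather than known)
phenotypic correlations — the sample-correlation sensitivity mode exists
precisely because real analyses only have estimates.

## Numerical choices

* Correlation matrices must be symmetric within 1e-10 with unit diagonal;
  eigenvalues may undershoot 0 by at most 1e-8 (clipped to 0), else the
  matrix is rejected.
* Eigenvalues are computed with a symmetric eigensolver and sorted
  descending before the `λ > 1` indicator sum.
* Ties among p-values are broken by original phenotype index (stable
  sort); with tied p-values the TATES submatrix ordering follows that
  stable permutation, so the result depends on the input order only
  through the correlation submatrix.
* Compound symmetry requires `r ∈ (−1/(m−1), 1]`; the boundary `r = 1`
  (singular but PSD) is supported via the eigenvalue factor.

## Known limitations

* Only the global null is simulated; power under alternatives is out of
  scope.
* One SNP at a time; no gene-based aggregation over SNP sets.
* The p-value correlation polynomial is a fixed approximation calibrated
  for two-sided normal-theory tests; for other univariate tests a custom
  map should be registered.
* `M_eff` uses the variance-of-eigenvalues form; other effective-number
  definitions exist and can be swapped only by replacing `nyholt_meff`.
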