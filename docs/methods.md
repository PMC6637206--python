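# Methods

## Model and estimator

`condfdr` works on the marginal p-values of two GWAS, merged on shared
SNP identifiers. The conditional FDR of a SNP for the principal trait
*i* given conditioning trait *j* is the posterior null probability given
that both p-values are at or below the observed pair. Reading the joint
p-value distribution empirically gives the count-ratio estimate

    cFDR(p_i | p_j) = p_i * N(P_j <= p_j) / N(P_i <= p_i, P_j <= p_j),

capped at 1. Conventions that pin the estimator down exactly:

- **Counts are inclusive (`<=`)** on both axes, so ties need no
  tie-breaking randomness and the query SNP counts itself; on-panel
  denominators are therefore >= 1. An off-panel query with an empty
  joint count returns 1 with a warning (the most conservative value).
- **Per-SNP values are computed by exact counting** at the observed
  pairs — a sort plus Fenwick-tree sweep, O(n log n), JIT-compiled with
  numba — never by interpolating the exported look-up tables. The
  rectangular tables exist for export and visualisation and each cell
  equals a pointwise evaluation of the same counts.
- **Raw values are reported by default.** Monotonization (a running
  minimum from the least-significant end, per conditioning column of a
  table, or optionally along ranked principal p within
  conditioning-stratum bins for per-SNP values) is available but off,
  because raw count ratios are reproducible without further
  conventions. With vacuous conditioning (`p_j = 1`) the raw value is
  `p * n / rank` and its monotonized version is exactly the
  Benjamini–Hochberg adjusted p-value, which the tests verify against
  statsmodels.
- The conjunctional value is `ccFDR = max(cFDR_i|j, cFDR_j|i)`,
  evaluated per SNP with the roles swapped on the same panel. Two
  inequalities hold exactly and are property-tested: `cFDR >= p_i` and
  `ccFDR >= max(p_i, p_j)`.

Significance is a strict inequality (`statistic < alpha`, default
0.05); a value exactly at the threshold is excluded.

## Data preparation

Input files are delimited text with a header; a column dialect maps
source names onto `snp_id, chrom, pos, pvalue[, zscore]`. Rows failing
validation (p outside (0, 1], non-positive positions, blank ids,
z-scores inconsistent with `2*Phi(-|z|)` beyond 1e-6 relative) are
dropped and counted; duplicate ids keep the smallest p-value
(conservative for FDR and deterministic); chromosome labels lose any
`chr` prefix and non-autosomes are excluded by default. P-values below
1e-300 are clamped there (policy `clamp`; `reject` drops them instead)
so chi-square transforms and log axes stay finite.

Genomic control uses λ = median(χ²₁ quantile transform of p) / 0.4549,
the χ²₁ median fixed to four decimals. Correction divides the
chi-square deviates by λ and is **off by default**: the consortium
summary files this pipeline is aimed at ship already GC-corrected, so
correcting again would be doubly conservative. λ is always estimated
and logged; the flag `gc_correction: true` applies it to both traits.
No allele harmonisation is attempted — the estimator uses p-values
only and is sign-free.

## Synthetic study conditions

The generator draws, per SNP, a component from (π₀, π₁, π₂, π₁₂) and a
bivariate z-score with covariance

    [[1, ρ_null], [ρ_null, 1]]  +  component effect covariance,

where trait-1-only adds σ₁² to the first diagonal, trait-2-only σ₂² to
the second, and pleiotropic SNPs add both plus a cross term
ρ_pleio·σ₁·σ₂. Two-sided p-values are 2Φ(−|z|). Defaults: 10⁵ SNPs,
(π₀, π₁, π₂, π₁₂) = (0.979, 0.01, 0.01, 0.001), σ₁² = σ₂² = 16,
ρ_null = 0, ρ_pleio = 0.5, no inflation, 22 chromosomes. The mixture
weights and effect variance are a sparse polygenic regime with
moderately powered meta-analysis-scale signals (mean χ² = 17 at causal
SNPs); ρ_pleio = 0.5 expresses that pleiotropic effects on two related
traits tend to point the same way without being collinear. ρ_null
mimics the score correlation induced by overlapping samples between
cohorts; no analytical correction for overlap is applied downstream —
the parameter exists so its effect can be studied.

`lambda_inflation` multiplies the total z variance, which the
genomic-control estimator recovers (tested at 5% tolerance). An
optional block-exchangeable mode (`block_size`, `block_r`) correlates
consecutive SNPs, giving the clumping stage something to collapse;
marginal moments are preserved by mixing a block-level and a per-SNP
draw from the same component covariance.

What the generator does **not** emulate: realistic LD maps and MAF
spectra, MAF-dependent power, case/control ascertainment, fixed per-SNP
effect sizes carried across studies (a replication draw redraws effects
from the same component, i.e. signals persist in distribution, not in
value), and genomic clustering of causal variants. Passing tests
therefore demonstrate the estimator's properties under a clean mixture
model, not performance on any particular real cohort.

A replication dataset is generated by redrawing z-scores with the
discovery run's component labels under a shifted seed — an independent
study of the same underlying architecture, with no sample overlap.

## Diagnostics

Stratified Q-Q, fold-enrichment and TDR curves use nested conditioning
strata `p_j <= 1, 0.1, 0.01, 1e-3, 1e-4` and a nominal grid of 1,000
points equally spaced in −log₁₀ p over [0, 10]. Strata smaller than
100 SNPs (configurable) are skipped with a warning — quantile estimates
below that size are noise. Fold values where the all-SNP exceedance
proportion is zero are reported as missing (NaN), never infinity. TDR
is 1 − cFDR clipped to [0, 1], with empty joint counts giving cFDR 1
and TDR 0. No LD pruning is applied before curve construction by
default; `random_prune` (one random SNP per window, seeded) exists for
sensitivity analysis.

## Locus selection and replication

Clumping is greedy: the most significant unassigned SNP passing alpha
leads a locus and absorbs all unassigned significant SNPs within a
window (default 1 Mb, distance-only) on the same chromosome; with an LD
table supplied, membership additionally requires r² ≥ `r2_clump`. Ties
on the statistic break by (chromosome, position), making the partition
deterministic. Distance-only is the default because no LD reference
panel is bundled. When one principal trait is conditioned on two second
traits, the two per-SNP result sets are pooled by the per-SNP minimum
statistic and clumped once (`union_clump`) to produce a single
independent locus count.

A discovery locus replicates if its lead passes alpha in the
replication analysis, or if any replication-significant SNP on the same
chromosome has r² **strictly greater than 0.6** with the lead; the
satisfying proxy and its r² are recorded. Cross-chromosome proxies are
never accepted regardless of table content. Without an LD table only
exact-id matching is performed and the output flags it.

## Numerical and design choices

- Fenwick-sweep counting is exact integer arithmetic; the only floating
  work is the final ratio. A pure-Python fallback with identical
  semantics covers environments without numba.
- Exported TSVs print statistics in scientific notation with four
  significant digits; Manhattan tables carry −log₁₀ values with the
  0.05 line at 1.3010. Fixed config + seed reproduces every output
  byte-for-byte (tested).
- The display-time inflation correction some Q-Q presentations apply is
  exposed only as the `gc_correction` flag; no additional ad-hoc
  rescaling is performed.
- Simulation-based checks in the test suite run at 10⁵ SNPs and 50
  seeds for the FDR-control, power-gain and enrichment-ordering
  properties, and 10⁴–5·10⁴ SNPs elsewhere; these sizes give binomial
  noise small enough for the stated tolerances while keeping the suite
  quick.
- The enrichment-ordering property is exercised at π₁₂ = 0.01 (ten
  times the default pleiotropic fraction): with only ~100 pleiotropic
  SNPs per panel the deepest stratum's fold estimate rests on a few
  dozen hits and its seed-to-seed ordering is dominated by noise rather
  than by the property under test.

## Limitations

- The count-ratio estimator is conditionally conservative on average
  but is not a proof of FDR control per conditioning stratum; control
  is demonstrated by simulation under the stated mixture.
- No modelling of LD-induced dependence between test statistics in the
  estimator itself; clumping handles redundancy only after selection.
- Sample overlap between the two discovery GWAS inflates the null
  correlation of z-scores and can make conditional estimates
  anti-conservative; the generator exposes ρ_null to quantify this, but
  the pipeline applies no correction.
- ccFDR is reported for all SNPs, but it is a meaningful conjunction
  statistic only where both marginal estimates are stable; with very
  small panels the max rule inherits the noisier direction.
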