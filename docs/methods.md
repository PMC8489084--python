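# Methods

## Setting and assumptions

`tsmr` performs two-sample Mendelian randomization: the causal effect of an
exposure X on a binary outcome Y is estimated from per-variant summary
statistics taken from two non-overlapping GWAS. The instrumental-variable
assumptions are (1) relevance — each variant is robustly associated with X;
(2) independence — variants are unconfounded with Y; (3) exclusion — variants
affect Y only through X. Relevance is enforced mechanically by
`significance_filter` (default p < 5×10⁻⁸, strict inequality); the other two
are unverifiable from summary data and are probed by the diagnostics
(Egger intercept, Cochran's Q, MR-PRESSO, leave-one-out). Instruments are
assumed LD-independent; no pruning is performed.

## Data model and harmonization

Analyses consume `HarmonizedDataset`: per-variant
(β̂_X, σ_X, β̂_Y, σ_Y) on a common effect allele. `harmonize` inner-joins on
rsid, flips the outcome beta (and complements its EAF) when the outcome
study reports the opposite effect allele, attempts strand-complement
resolution before discarding, and drops palindromic variants (A/T, C/G)
whose exposure EAF is within 0.08 of 0.5 (i.e. 0.42–0.58) as
strand-ambiguous — a common community default; every drop is logged with
its reason.

Datasets are analyzed in their published orientation; `harmonize` can
optionally re-sign records so that all exposure betas are positive, but
this is off by default because the Egger intercept (unlike the IVW and
Egger slopes) is not invariant to orientation, and the bundled datasets
must be analyzed exactly as published.

The bundled instrument tables store the published values verbatim
(3 decimals, scientific-notation p-values). One published p-value
(4.74×10⁻³⁴³) underflows IEEE doubles; the reader clamps underflowed
positive p-values to the smallest representable float rather than
rejecting the row. The single published EAF column is interpreted as the
exposure-study effect-allele frequency; no estimator consumes outcome EAF.
A soft consistency check compares each row's reported p-value with
|beta/se| on the z scale and warns when they disagree by more than a factor
of two — a deliberately loose criterion, since rounding published betas and
SEs to three decimals moves extreme p-values by many orders of magnitude
while barely moving z.

## Estimators

**Wald ratio.** r_i = β̂_Yi/β̂_Xi with first-order (delta) SE σ_Yi/|β̂_Xi|.
Exposure-side noise is ignored in all weights (first-order weights); this
matches the conventional estimators and keeps IVW identical to a weighted
regression through the origin with weights 1/σ_Yi².

**IVW.** Point estimate Σw_i r_i / Σw_i with w_i = β̂_Xi²/σ_Yi², identical
in both modes. `fixed` SE is (Σw_i)^(−1/2); the default
`multiplicative_random` SE multiplies it by max(1, √(Q/(k−1))) — inflation
under excess heterogeneity, never deflation. p-values and CIs are normal
(z = 1.959964).

**Weighted median.** Ratios sorted ascending; variant i sits at the
cumulative-weight midpoint s_i = Σ_{j≤i} w′_j − w′_i/2 with normalized
weights; the estimate is the linear interpolation of ratio against s at
s = 0.5. The SE is the standard deviation of the estimate over parametric
bootstrap replicates (default n_boot = 1000) redrawing every β̂ from a
normal with its reported mean and SE; the seeded generator makes it
bit-reproducible.

**MR-Egger.** Weighted least squares of β̂_Y on β̂_X with intercept,
weights 1/σ_Y². Inference follows the ordinary least-squares convention at
small k: SEs carry the residual scale √(RSS_w/(k−2)) without flooring, and
p-values use the t distribution with k−2 df. At the bundled datasets'
instrument counts (5–7) this convention reproduces the published intercept
p-values closely, which a floored normal approximation does not. The
degenerate all-equal-β̂_X design is rejected as collinear.

**MR-PRESSO.** Observed statistic
RSS = Σ_i (β̂_Yi − β̂₋ᵢ β̂_Xi)²/σ_Yi², with β̂₋ᵢ the IVW slope excluding
variant i (algebraically equal to the ratio-scale form Σ w_i (r_i − β̂₋ᵢ)²).
The null distribution redraws β̂*_X ~ N(β̂_X, σ_X) and
β̂*_Yi ~ N(β̂₋ᵢ β̂_Xi, σ_Yi) and recomputes the statistic, n_sim times
(default 1000); the global p-value is the add-one estimator
(1 + #{RSS* ≥ RSS})/(n_sim + 1), never exactly zero. Per-variant residuals
are compared against their own simulated distributions and flagged below
0.05/k (Bonferroni; the threshold is a config value). When variants are
flagged, IVW is recomputed without them; an optional distortion test
(off by default) compares the raw-vs-corrected shift against removing
equally many random non-flagged variants.

*Calibration caveat.* The simulation null regenerates outcome betas around
the per-variant leave-one-out slopes. When the pooled slope is imprecise —
few instruments explaining little variance, as in the bundled datasets
(k = 5–7, slope SE ≈ 0.3) — the simulated datasets carry extra
slope-uncertainty variance and the global test is markedly conservative
(its type-I rate can be far below nominal). With well-powered panels
(tens of strong instruments) the test is close to nominal; the test suite
verifies calibration in that regime and only the direction (rarely
rejects) at the bundled scale.

## Diagnostics

Cochran's Q = Σ w_i (r_i − β̂_IVW)², chi-square with k−1 df under
homogeneity, using exactly the IVW ratios and weights, so Q = 0 iff all
ratios coincide. `single_snp_table` exports funnel-plot coordinates
(ratio, SE, precision = 1/SE) rather than drawing figures. Leave-one-out
recomputes IVW k times, dropping one variant per row, in input order.

## Power

The binary-outcome power routine uses the standard NCP approximation for a
two-stage IV analysis of a case/control trait: with case fraction
K = n_cases/N and alternative odds ratio OR per SD of exposure,
b = K(OR/(1+K(OR−1)) − 1), v = (K(1−K) − b²)/(N·R²), NCP = b²/v, and power
is the upper tail of the non-central χ²(1, NCP) at the central (1−α)
quantile. Power equals α exactly at OR = 1. `find_detectable_or` bisects
over OR > 1 to absolute tolerance 10⁻⁶; because b → 1−K as OR → ∞, the
variance term turns negative at large OR (power is undefined there), so
the upper bracket is shrunk to the valid regime before bisection. A
mirrored bracket on (0, 1) handles protective effects.

## Synthetic data

`simulate_pair` draws, for instrument i with true effect γ_i: observed
β̂_Xi ~ N(γ_i, σ_Xi); true outcome effect Γ_i = b·γ_i + α_i (+ shift for
planted outliers) with α_i = 0, N(0, τ²) (balanced pleiotropy) or
N(μ, τ²) (directional); observed β̂_Yi ~ N(Γ_i, σ_Yi). P-values come from
the simulated z-scores. Instrument effects, EAFs and outlier positions are
realized once per configuration (from `config.seed`); the per-call `seed`
varies only the sampling noise, so Monte-Carlo replicates share a fixed
instrument panel — the two-sample asymptotic setup. Alleles/EAFs are
cosmetic (A/G, EAF uniform 0.1–0.9): no estimator uses them, they only
exercise the I/O layer. `table1_like_config` reproduces the bundled
exposures' instrument counts, effect sizes and SEs with the causal effect
and pleiotropy left free, for studying estimator behaviour at exactly the
reproduced study's precision regime.

What the generator does not emulate: linkage disequilibrium between
instruments, sample overlap between studies, winner's-curse bias in
instrument selection, and non-Gaussian sampling error. Passing tests
therefore certify the estimators under the idealized two-sample model, not
robustness to those violations.

## Problem sizes and numerical choices

Monte-Carlo tests use 500 replicates for calibration/coverage/bias checks
and 100 seeds for outlier-recovery, with MR-PRESSO at n_sim ≈ 200 inside
replicated runs and 1000 for single analyses — sizes at which the checked
bands (e.g. type-I in [0.02, 0.09], coverage in [0.92, 0.975]) are stable.
All CIs use the normal quantile 1.959964; ties in the weighted median are
resolved by stable sorting; report files format floats at six significant
digits with fixed row ordering, so identical seeds regenerate reports
byte-for-byte.

## Known limitations

- First-order weights throughout; no second-order or exact-weight IVW,
  no SIMEX-corrected Egger, no mode-based or multivariable estimators.
- The MR-PRESSO global test is conservative with few weak instruments
  (see above); its outlier subtest inherits the same simulation null.
- Harmonization resolves strand by allele complement only; no proxy-SNP
  lookup, liftover or reference-panel frequency matching.
- The power routine covers binary outcomes only and treats instrument R²
  as a known constant.
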