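# Methods

`adipomr` implements summary-data Mendelian randomization (MR) for a
continuous adiposity exposure (body mass index or a body-composition index,
in kg/m²) against binary disease outcomes, together with a generative
simulator that produces two-sample GWAS summary statistics under a fully
known structural model. This note records the statistical model, the
defaults and why they were chosen, the numerical decisions, and what the
simulation-based validation does and does not demonstrate.

## The structural model behind the simulator

For individual *i* with dosages `g_ij ∈ {0,1,2}` at `J` independent
biallelic SNPs:

```
X_i = Σ_j γ_j g_ij + ε_i                      (exposure, unit variance)
logit P(Y_i = 1) = β₀ + θ X_i + Σ_j α_j g_ij  (binary outcome)
```

* `γ_j` — per-allele SNP–exposure effects. Two distributions are available:
  `normal` (effects drawn N(0,1) then rescaled; realistic heterogeneity in
  instrument strength) and `equal` (each SNP explains `h²/J` of the exposure
  variance, so inverse-variance weights are homogeneous). In both cases the
  theoretical instrument variance `Σ_j 2p_j(1−p_j)γ_j²` is scaled to the
  target `exposure_h2` on a unit-variance exposure, so the realized multiple
  regression R² converges to `h²` as n grows (validated at n = 100,000 to
  within ±0.003).
* `α_j` — direct (pleiotropic) SNP–outcome effects. `none`: all zero.
  `balanced`: N(0, σ²), mean-zero, InSIDE-compatible — IVW remains
  consistent, heterogeneity grows. `directional`: N(μ, σ²) with the sign
  aligned to `sign(γ_j)`; instruments are conventionally oriented
  exposure-increasing, and the alignment makes the direct effects act in a
  common direction on the ratio scale (the scenario MR-Egger's intercept is
  designed to detect). Only a `pleiotropy_frac` fraction of SNPs receives
  direct effects. `planted_outliers`: `n_outliers` SNPs receive a fixed
  direct effect `outlier_effect`, likewise sign-aligned so all outliers
  distort the pooled estimate the same way.
* `θ` — the causal log odds ratio per exposure unit; every estimator
  targets it.
* `β₀` is solved by Brent bisection on the simulated linear predictor so
  the marginal event rate hits `outcome_prevalence`; realized rates land
  within ±0.005 at the default cohort sizes.

Two-sample design: SNP–exposure associations are estimated by univariable
linear regression in cohort A, SNP–outcome log odds ratios by univariable
logistic regression in a disjoint cohort B. When a second, correlated
exposure is configured (fat-mass / fat-free-mass style), both exposures are
scanned in cohort A; their per-SNP effect vectors share a configurable
correlation.

Default cohort sizes are the flagship scale of the study design this
package reproduces: 339,224 for the exposure scan and 367,703 for the
outcome scan, with J = 96 instruments explaining 1.6% of exposure variance,
a causal OR of 1.10 per unit, and 10% outcome prevalence (a representative
value for common cardiovascular conditions; real outcomes vary roughly
from <1% to ~30% and differ here only through `outcome_prevalence`).
Validation ensembles scale the cohorts down to 50,000 + 50,000 — chosen as
the smallest size at which the per-replicate IVW standard error (~0.12 on
the log-OR scale) still separates the designed effects from noise.

**Per-SNP association scans.** Because dosages take only three values, each
univariable regression is a function of six sufficient statistics (genotype
counts and per-genotype phenotype sums), collected in one `bincount` pass
per SNP. The linear scan uses closed-form least squares with t-based
p-values; the logistic scan runs a vectorized 2-parameter Newton–Raphson on
the 3×2 tables (convergence tolerance 1e-10, cap 40 iterations; divergence
`|β| > 50`, typically separation, excludes the SNP with a log entry). Both
scans are verified against `statsmodels` OLS/Logit in the test suite.
Monomorphic SNPs and zero-variance phenotypes are excluded with logged
reasons. No principal-component adjustment is applied: simulated cohorts
have no population structure, so the PC step of the emulated design is a
deliberate no-op.

**Randomness.** One master `SeedSequence` spawns independent streams per
stage (model draw, each cohort's genotypes, each cohort's phenotypes), and
the genotype stage spawns one stream per SNP, so enlarging the panel leaves
earlier columns unchanged. Identical configs produce byte-identical output
files (floats are written with `%.10g`).

## Harmonization

Exposure and outcome records are intersected on variant ID and the outcome
(and second-exposure) effects re-expressed on the exposure's effect allele:
matching allele pairs are kept, swapped pairs sign-flipped, strand
complements resolved via A↔T / C↔G. Palindromic SNPs (A/T, C/G) are
letter-ambiguous across strands and are resolved by effect-allele
frequency: both EAFs must be present and farther than `w = 0.08` (default,
configurable) from 0.5; if they fall on opposite sides of 0.5 after letter
alignment the conflict is unresolvable and the SNP is dropped — the
conservative choice; frequencies are never used to silently flip a sign.
Every drop is logged as `(variant_id, reason)` and the intersection is
conserved: |kept| + |dropped| equals the exposure panel size.

Instrument selection applies strict `p < 5×10⁻⁸`, and — only where the
optional columns are present — imputation quality `info > 0.8` and
Hardy–Weinberg `p ≥ 10⁻⁶`. The HWE cut-off is a guess (the emulated design
states only "in Hardy–Weinberg equilibrium") and is configurable; missing
optional columns never exclude a record, since published instrument tables
often lack them.

## Estimators

With harmonized pairs `(γ̂_j, σ_Xj, Γ̂_j, σ_Yj)`:

* **Wald ratios** `r_j = Γ̂_j/γ̂_j`, first-order delta SE `σ_Yj/|γ̂_j|`.
  Ignoring `σ_Xj` here is what makes IVW algebraically identical to the
  weighted no-intercept regression of `Γ̂` on `γ̂` (checked to 1e-10);
  exposure-side noise re-enters through the bootstrap and the PRESSO
  resampling.
* **IVW**: `β̂ = Σ w_j r_j / Σ w_j`, `w_j = 1/se(r_j)²`. Multiplicative
  random effects (the default) inflate the fixed SE by `√(Q/(J−1))` floored
  at 1, where Q is Cochran's statistic; the floor means the random-effects
  SE never undercuts the fixed one. The flavour follows the summary-MR
  convention of inflating rather than adding a between-SNP variance
  component; J = 1 collapses to the single ratio with Q undefined.
* **Weighted median**: the median of the weighted empirical ratio
  distribution, inverted-CDF convention — the smallest ratio at which the
  cumulative normalized weight reaches 0.5, averaging the straddling pair
  at an exact tie. This makes equal weights reduce to the sample median and
  a SNP carrying >50% of the weight determine the estimate exactly; it
  differs from the centered-interpolation variant by O(1/J). SE from a
  seeded parametric bootstrap (default 1,000 resamples of both `γ̂` and `Γ̂`
  from normals with their reported SEs; the replicate count is configurable
  because conventions differ). Consistency requires ≥50% of the *weight*
  to come from valid instruments — see the contamination caveat below.
* **MR-Egger**: SNPs oriented exposure-positive (negating both members of a
  pair, without which the intercept is unidentified), then weighted least
  squares of `Γ̂` on `γ̂` *with* intercept, weights `1/σ_Yj²`. The slope
  estimates the causal effect under InSIDE; the intercept estimates mean
  directional pleiotropy. Both coefficients' SEs carry the multiplicative
  inflation `√(RSS_w/(J−2))` floored at 1. P-values are normal by default
  (`t_dist=True` for t with J−2 df); with ~96 instruments the difference is
  cosmetic.
* **Multivariable MR**: weighted no-intercept regression of `Γ̂` on both
  exposures' instrument effects; coefficients are mutually adjusted direct
  effects, inflation `√(RSS_w/(J−K))` floored at 1. Collinear nonzero
  effect columns raise; an identically-zero column is dropped with a
  warning and the model reduces to univariable IVW for the other exposure
  (the nested-model identity used in testing).

## MR-PRESSO

The observed statistic is the weighted RSS of each SNP's outcome
association about its leave-one-out fixed-effect IVW prediction; the
leave-one-out fit uses fixed (not random) effects for stability at small J.
The null ensemble redraws `γ*_j ~ N(γ̂_j, σ_Xj)` and
`Γ*_j ~ N(β̂_{−j}γ̂_j, σ_Yj)` and recomputes the full leave-one-out RSS per
draw. Empirical p-values use `(1 + exceedances)/(1 + n_sim)` and can never
be exactly zero. Per-SNP outlier p-values are Bonferroni-scaled by J before
the exclusion threshold (0.10); consequently `n_sim` must exceed `J/α`
for any SNP to be flaggable — 960 at J = 96 — which motivates the default
`n_sim = 1000`. A `raw` mode skips the scaling for users who read the 0.10
rule as applying to unadjusted p-values. The outlier-corrected estimate is
the random-effects IVW on the retained SNPs; the distortion test refers the
corrected-minus-raw difference to differences from removing random subsets
of the same size (two-sided on magnitude), and is reported as absent when
nothing was flagged.

## Diagnostics

* Variance explained: `R² = Σ 2p_j(1−p_j)γ̂_j²/var(X)` from summaries, or
  multiple-regression R² from raw data.
* F statistic: `(n−k−1)/k · R²/(1−R²)`. Note the flagship configuration
  (R² = 0.016, n = 339,224, k = 96) gives 57.4 by this formula — reported
  instrument-strength values computed other ways (e.g. mean per-SNP F) can
  differ by a few units; the formula, not any particular printed value, is
  what is asserted. The F > 10 rule of thumb is surfaced as a flag.
* Conditional F (two exposures): exposure k's effects are residualized on
  the other exposure's by weighted no-intercept regression (weights
  `1/σ_Xk,j²`); the weighted residual sum of squares divided by `J − 2` is
  the conditional strength. Orthogonal effect vectors recover the
  univariable mean per-SNP F up to `J/(J−2)`; collinear vectors drive it to
  0 (warning, not error). At body-composition-like settings (82 SNPs,
  R² 0.8%/0.7%, effect correlation 0.5, n ≈ 362,000) it lands near 28/26.
* Power: two-sided normal approximation
  `power = Φ(√NCP − z) + Φ(−√NCP − z)` with
  `NCP = N·R²·cf(1−cf)·log(OR)²` and case fraction `cf`. The two-sided form
  returns exactly α at OR = 1 and is symmetric in cases/controls and in
  OR ↔ 1/OR. It treats the instrument–exposure effect as known; the
  Monte-Carlo check in the test suite adopts the same assumption.

## Multiple testing and reporting

The primary analysis across `m` outcomes uses the Bonferroni threshold
`α/m` (0.05/14 = 3.571×10⁻³, displayed at two significant figures as
3.6×10⁻³). Tiers use strict inequalities: `p < α/m` significant,
`α/m ≤ p < α` suggestive, else null — a p-value exactly at the corrected
threshold is suggestive. Report rows are sorted by descending primary OR;
displayed ORs/CIs use two decimals and p-values two significant figures,
while serialized estimates keep full precision (`report OR = exp(beta)`
exactly).

## What the validation shows — and does not

The acceptance-style ensembles demonstrate, under the generator: exact
algebraic identities; IVW/Egger type-I error within [0.02, 0.08] at 200
nulls; mean IVW recovery of log(1.10) within ±0.01 with 90–99% CI coverage
at the full flagship cohort sizes (at 50k + 50k cohorts the two-sample
weak-instrument attenuation `h²/(h² + J(1−h²)/n)` ≈ 0.89 alone consumes
the ±0.01 budget — a property of the design, not the code); near-perfect
detection and correction of 5 planted outliers among 96 equal-strength
instruments; and the weighted median beating IVW in ≥80% of 40%-contaminated
replicates. Two structural caveats: at 40% one-directional contamination
the weighted median converges to the 0.5/0.6 quantile of the valid ratio
distribution — about one per-SNP ratio SE above the truth — so it reduces
bias by roughly an order of magnitude without eliminating it; and planted
outliers on near-zero-weight instruments are detectable but barely distort
the pooled estimate, which is why the outlier experiments use the
equal-strength panel.

The generator does not simulate linkage disequilibrium, genotyping or
imputation error, relatedness, population stratification, sample overlap
between the two cohorts, or outcome-specific aetiology beyond prevalence
and effect parameters. Passing tests therefore validate the inference
machinery under the stated model, not the robustness of any real-data
conclusion to those complications.
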