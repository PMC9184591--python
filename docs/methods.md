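# Methods

## Generative model

A cohort of `n_subjects` (default 1000) has, per subject, a treatment arm
T ~ Bernoulli(`treatment_prob`, default 0.5 for 1:1 randomization), an age
X ~ Uniform(18, 65) years (kept continuous; the model is linear in X so
rounding would be immaterial), a genotype G ~ Binomial(2, MAF) allele count
(default MAF 0.2), and two positive responses simulated on the natural-log
scale:

    ln y0       = b0 + βG0·G + ε0,                 ε0 ~ N(0, sd_eps0²)
    ln y1 − ln y0 = βT·T + βX·X + βy0·ln y0 + βG·G + βGT·G·T + ε1

with defaults b0 = 4.6, βT = −0.25, βX = −0.01 and standard-normal errors.
Every response entering a log transform is floored at 1 on the natural scale
(a ~2·10⁻⁶ tail event at the default intercept), and the flooring is applied
both to the noiseless responses and, again, after measurement error — the
convention chosen where either reading was defensible.

βG0·βy0 is the mediator effect: the genotype-to-CFB pathway routed through
the baseline. Substituting the first equation into the second shows a
baseline-unadjusted analysis tests βG + βG0·βy0, not βG.

**Measurement error** multiplies observed responses by (1 + rᵢ) with
rᵢ ~ N(μᵢ, σ²), σ = 1/4 by default (≈95% of relative errors within ±0.49 of
their mean). Three presets: `white` (μ0 = μ1 = 0), `same` (both +0.25),
`opposite` (−0.25 / +0.25). Factors at or below zero are mapped to the floor.

**Variant panels.** `simulate_panel` assigns each variant to a class
(baseline-associated, direct-CFB, interaction, null) by configurable
fractions. The default `single_causal` rule gives each variant its own
phenotype replicate generated from its own truth tuple — the
one-variant-at-a-time design of the type-I-error study — so a panel is
simultaneously a replicate batch. An `additive` rule (one shared phenotype
summing all causal effects) is provided for more realistic scans but is not
used in the validation suite. The simulator deliberately omits LD,
stratification, relatedness and missingness: panels exercise the analysis
models' statistical behaviour, not variant-calling or QC pipelines, so
passing tests say nothing about those real-data complications.

## Analysis models

Twelve models (see the table in `cfbgwas.models`). Conventions that the
literature leaves open, fixed here:

- **INT**: rank-based inverse normal transform with Blom offset 3/8
  (the GWAS standard; exposed as a parameter). The scalar implementation
  averages tied ranks; the vectorized engine breaks ties by position, which
  is immaterial for continuous residuals.
- **Step 2 of two-step models** regresses the INTed residuals on intercept +
  genotype only (no covariates re-enter). The intercept is harmless — INTed
  residuals have mean ≈ 0 — and guards against floor-truncation asymmetry.
- **M4** adjusts for the raw baseline y0 (not ln y0), matching its
  percent-change phenotype.
- **2df test**: Wald chi-square on (β̂G, β̂GT) with their estimated 2×2
  covariance, p from χ²₂. (A likelihood-ratio variant would be
  asymptotically equivalent; Wald is the large-n GWAS convention.)
- **Single-coefficient tests** use the t distribution with residual df,
  which matches the normal reference at GWAS sample sizes but is less
  liberal at small n.
- **Cochran's Q** fits ln yᵢ ~ intercept + T + G + X for i = 0, 1 and forms
  the inverse-variance-weighted heterogeneity statistic, which reduces to
  (β̂G1 − β̂G0)²/(s0² + s1²). The two coefficients share ε0 and are positively
  correlated, so the χ²₁ reference overstates the variance and the test is
  conservative — confirmed empirically (rejection ≈ 0.0009 at nominal 0.05,
  10⁴ replicates of the global null).
- **Monomorphic genotypes** return a flagged result with p = 1 instead of
  raising, so panel scans never abort; rank-deficient designs raise a
  `DesignError` naming the offending column.

## Monte-Carlo evaluation

`estimate_rates` simulates replicates per grid cell, fits every requested
model, and reports rate = P(p < α) per nominal level, with Monte-Carlo
standard error √(α(1−α)/reps) computed from the nominal α and the inflation
flag rate > α + 3·se. `inflation_threshold(α, reps)` is the equivalent
rate/α criterion (≈1.67 at α = 10⁻⁶ with 2·10⁷ replicates). Power is the
same rate under an alternative cell, reported **without** adjusting for any
type-I inflation of the model; `compare_power` pairs two models on shared
replicates and quotes the paired binomial se of the difference, which is
much tighter than an unpaired comparison.

Replicate fitting is vectorized: designs are stacked (replicates × subjects
× columns) and solved with batched normal equations, with the two-step INT
done by row-wise ranking. A reference engine that fits each replicate through
statsmodels on the same random draws is retained, and the suite asserts the
two agree to ~10⁻⁸ relative error. A master `SeedSequence` spawns one child
stream per fixed-size chunk, so results are exactly invariant to the worker
count (they do depend on `chunk_size`, which is therefore part of a run's
configuration and recorded in CLI manifests).

**Problem sizes.** The validation suite runs the mediator-null cell at 10⁶
replicates with α = 10⁻⁴ for the unadjusted-inflation check, 2·10⁵ replicates
for adjusted-model control at α ∈ {0.05, 10⁻², 10⁻³, 10⁻⁴}, and 10⁴
replicates per power cell at α = 10⁻³. These are this package's chosen
desk-scale settings; the grid, replicate counts and α levels are all
configurable up to the cluster-scale protocol (α = 10⁻⁶, 2·10⁷ replicates).
At α = 10⁻⁴ the analytic expectation for the unadjusted ratio in the
mediator cell (βG0 = 0.1, βy0 = −0.2) is ≈2.1: the test-statistic shift is
δ = |βG0·βy0|·√(n·2·MAF·(1−MAF))/√(βy0²·sd0² + sd1²) ≈ 0.35, giving a
two-sided tail ratio [Φ̄(z − δ) + Φ̄(z + δ)]/α. The same oracle at α = 10⁻⁶
predicts a peak ratio ≈2.9 over the null grid, consistent (within that
scale's own Monte-Carlo error of ≈0.4 on the ratio) with a worst case near
3.5 at cluster scale.

## GWAS scan diagnostics

- **λ (genomic inflation)** uses the median-based estimator: observed median
  of χ²₁-transformed p-values over 0.455. The choice of estimator is pinned
  in tests against the quantile oracle.
- **QQ band**: pointwise 95% interval from the Beta(k, m+1−k) distribution of
  uniform order statistics, validated against brute-force simulated order
  statistics.
- **Mediator subset**: variants with baseline-association (M7) p < 10⁻³.
  On a synthetic panel with 10% baseline-associated variants (βG0 = 0.3,
  βy0 = −0.2), unadjusted models reach subset λ ≈ 2.8–2.9 while adjusted
  models stay ≈ 0.9–1.1 — the qualitative signature of mediator-driven
  inflation concentrating on baseline-associated variants.

## Known limitations

- The analytic inflation oracle ignores the INT's mild nonlinearity and the
  t-vs-normal difference; both are ≪ Monte-Carlo error at n = 1000.
- The `additive` panel rule shares one phenotype across variants, so its
  per-variant tests are correlated; λ sampling bands widen accordingly.
- No mixed models, robust standard errors, logistic outcomes, LD, or QC
  filtering; covariates such as ancestry PCs are accepted only as plain
  numeric columns.
- CLI grid configs are validated by explicit field checks with named-field
  error messages rather than a formal schema.
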