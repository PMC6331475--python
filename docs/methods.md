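# Methods

## The question

A pre-post design measures the same variable on n cases at two occasions.
Average-based change (ABC) statistics summarize the displacement of the
distribution center; individual-based change (IBC) statistics count the
cases whose change is statistically reliable. This package quantifies the
mapping between the two by Monte-Carlo simulation and packages the resulting
link functions for applied use.

## Data-generating model

Each simulated cohort is built in three steps.

1. **Marginals.** Two independent vectors of n scores are drawn from the
   Pearson distribution system with mean 0, SD 1 and target skewness g1 and
   excess kurtosis g2. The system solves
   `p'/p = −(x + c1)/(c0 + c1·x + c2·x²)` with coefficients fixed by the
   first four moments; the sign pattern of the quadratic selects the type:

   | type | region | sampler |
   |------|--------|---------|
   | 0 | g1 = 0, g2 = 0 | normal |
   | I/II | real roots straddling 0 | shifted/scaled beta |
   | III | c2 = 0 | shifted/scaled gamma |
   | IV | complex roots | inverse CDF in arctan space |
   | V | double root | shifted inverse gamma |
   | VI | real roots, same side | shifted/scaled beta-prime |
   | VII | g1 = 0, g2 > 0 | rescaled Student t |

   All types except IV are frozen scipy distributions, so their population
   moments can be verified in closed form; the tests do exactly that, to
   1e-6, for every grid shape. Type IV (hit by the (±1, 2) grid shapes) has
   no scipy counterpart: substituting `x = λ + a·tan(φ)` turns its density
   into `cos(φ)^(2m−2)·e^(−νφ)` on (−π/2, π/2) — bounded, smooth and
   log-concave — where a tabulated inverse CDF on 2¹⁶ grid points is exact
   to well below Monte-Carlo resolution (population moments verified by
   quadrature). Negative skewness is sampled by mirroring the positive-skew
   member. Moment pairs with `g2 ≤ g1² − 2` are rejected: below the bound no
   distribution exists, and on it only two-point laws without a density.

2. **Dependence.** The pre vector is kept as is; the post vector is the
   Cholesky mix `post = ρ·pre* + √(1−ρ²)·post*`, giving population
   correlation ρ. For non-normal marginals the mixing attenuates the
   post-occasion skewness (e.g. by the factor ρ³ + (1−ρ²)^{3/2}); this
   drift is accepted, not corrected — the generated scores are "similar"
   to the nominal shape, which is the intended behavior.

3. **Effect injection.** A constant shift is added to every post score so
   that the standardized mean of the differences is centered on the design
   value δ. The shift equals δ times the *sample* SD of the pre-shift
   differences, which makes the realized effect size exactly
   `d = d₀ + δ` (baseline d₀ plus the injected effect) and each case's
   standardized index exactly `SID_i = SID₀ᵢ + δ`. This choice is what
   reproduces the published link coefficients; shifting by the population
   value √(2(1−ρ)) instead yields a visibly flatter and noisier link
   (slope ≈ 26.9 instead of 28.8, R² ≈ 0.94 instead of 0.96 for the normal
   ρ = 0.5, n = 25 row). The population σ_dif form remains available in
   `inject_effect(y, delta, rho)` (per-case shift δ·1, δ·0.775, δ·0.447 at
   ρ = 0.5, 0.7, 0.9).

   Because pre and post are imperfectly correlated, a constant shift still
   produces a different realized change for every case; the control group,
   when present, is an independent cohort from the same condition with
   δ = 0.

## Estimators

* `d = (M_post − M_pre)/S_dif`, with S_dif the n−1 sample SD of the
  differences. All sample SDs in the package use the n−1 denominator.
* Interaction ω² for the 2×2 mixed design:
  `ω² = gl(F−1)/(gl(F−1) + N)` with gl = 1 and N the total number of
  scores (4n for equal groups — both groups, both occasions). F is computed
  as the one-way ANOVA F on difference scores between groups, which is
  algebraically identical to the mixed-model interaction F (and to the
  squared independent-samples t); the tests verify this identity against a
  brute-force sums-of-squares decomposition. Negative estimates (F < 1) are
  retained so that the link regressions are not distorted near δ = 0.
* `SID_i = D_i/S_dif`; `RCI_i = D_i/√((S²_pre + S²_post)(1 − r))` with the
  reliability r defaulting to the sample pre-post correlation (the choice
  with the lowest false-positive rate; an explicit value can be passed).
* A case is a reliable change only when its index **strictly exceeds** the
  cutoff: 1.645 one-tailed (single group — injected effects are positive,
  so the test is right-tailed), ±1.96 two-tailed (control-group design,
  where worsening matters as much as improvement). Both are configurable.
* Percentage = 100·(improvements)/n; net percentage
  `(P⁺_exp − P⁻_exp) − (P⁺_ctrl − P⁻_ctrl)`, recorded unclipped (raw range
  [−200, 200]).

## Link functions

Per condition row — fixed (shape, ρ, n, design), pooling all 13 δ values ×
reps — the package fits four families with the percentage as response:
polynomials of degree 1–3 by OLS (classical standard errors), and the
two-parameter logistic `100/(1 + exp(−(b0 + b1·x)))` by nonlinear least
squares with multi-start initialization. R² is `1 − SSE/SST` on the raw
percentage scale for all families, so they are directly comparable and the
polynomial sequence is provably nested. Predictions are clipped to
[0, 100] (percentage) or [−100, 100] (net percentage).

The logistic parameterization is a design choice: with asymptotes pinned at
0 and 100 it is the simplest curve consistent with a bounded percentage.
Under it the single-group logistic fits about as well as the cubic
(R² ≈ 0.98), whereas the published single-group logistic R² values are far
lower (0.68–0.78) — evidently a different, unstated parameterization; the
control-group values agree (≈0.925 vs 0.926). No packaged coefficient or
conversion depends on the logistic family.

`convert_effect_to_percentage` applies a packaged table of published linear
coefficients (n = 25 provenance, keyed by design × shape × ρ) to translate
an effect size into an approximate percentage without raw data; because the
coefficients vary little across conditions, selecting a neighbouring row
changes the estimate by only a few points.

## Study orchestration and seeding

The default grid is 13 δ × 3 n × 3 ρ × 7 shapes = 819 cells per design at
500 samples each; a condition row (one scatterplot) pools 6,500 samples.
Each row draws from an independent `SeedSequence` keyed by (master seed,
design, shape, ρ, n), so results are invariant to execution order and rows
can run concurrently. Degenerate samples (zero-variance differences —
probability zero under continuous generation, guarded anyway) are redrawn
once and logged. A full single-group study at default scale runs in minutes
on one CPU; the acceptance script reproduces the three headline rows
(normal shape, n = 25) in seconds.

## What the simulation does and does not emulate

It emulates: unit-variance occasions with identical marginal shape at pre
and post, a constant-within-sample treatment shift, homogeneous groups, and
exhaustive crossing of effect size, sample size, correlation and shape.
It does not emulate: variance or shape change between occasions,
measurement error (indices are computed from observed scores; error
attenuates ABC and IBC alike), heterogeneous treatment effects beyond what
imperfect correlation induces, or missing data. Passing tests therefore
certify the mapping between ABC and IBC under these conditions, not the
behavior of any particular instrument in the field.

## Numerical choices and edge cases

* Pearson type selection tolerances: |c2| < 1e-10 → type III;
  |κ − 1| < 1e-10 → type V (κ = c1²/(4c0c2)). The singular line
  10β₂ − 12β₁ − 18 = 0 of the coefficient formulas raises a feasibility
  error (no grid shape is near it).
* Type IV inverse-CDF grid: 2¹⁶ + 1 φ-points, trapezoid CDF; cached per
  (g1, g2).
* Zero-variance denominators raise `DegenerateSampleError`; constant link
  responses and rank-deficient designs raise `FitError`; reliability ≥ 1
  and |ρ| ≥ 1 are validation errors. Ties at the cutoff are not changes.
* CSV IO writes floats with `%.17g` and reads with round-trip parsing, so a
  written table re-reads bit-exactly.

## Known limitations

* The logistic family's published goodness-of-fit cannot be reproduced
  without knowing the original parameterization (see above).
* Sample skewness/kurtosis of the extreme grid shapes (|g1| = 3, g2 = 18)
  converge slowly: their 8th moment is near-divergent, so the sample g2 at
  n = 10⁶ still scatters by ±2 around the (exactly verified) population
  value. Tests on sample moments use estimator-aware tolerances.
* The packaged conversion table carries n = 25 coefficients only; with
  larger n the coefficients are similar but the residual scatter is
  smaller.
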