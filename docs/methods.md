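# Methods

## Estimands and notation

All estimators operate on (or reduce to) the 2×4 layout of a binary
susceptibility factor S, binary environmental exposure E and binary
disease D:

| E | S | cases | non-cases |
|---|---|-------|-----------|
| − | − | a     | B         |
| − | + | c     | D         |
| + | − | e     | F         |
| + | + | g     | H         |

With the S−E− stratum as reference, `RR_s = c(a+B)/(a(c+D))`,
`OR_s = cB/(aD)`, and analogously for E and the joint stratum.  The
multiplicative interaction contrast ratio (ICR) is the joint effect over
the product of single effects; the additive contrast (RERI) is the joint
effect minus the sum of single effects plus one.  Design subscripts:
`c/nc` (full sample of cases and non-cases), `cc` (case-control at
control-sampling fraction p), `co` (cases only).  Closed forms:

* `ICR_co = ag/ce` — the S–E odds ratio among cases;
* `ICR_c/nc (RR basis) = ICR_co × (c+D)(e+F)/((a+B)(g+H))` — exact;
* `ICR_cc = ICR_co × df/bh` — exact, with controls b,d,f,h; under
  expected-value sampling `(b,d,f,h) = p(B,D,F,H)`, so p cancels and
  `ICR_cc` equals the OR-basis `ICR_c/nc` for every p.

The case-only design earns its keep through the variance ordering
(asymptotic variances of the log estimates):

```
Var_co  = 1/a + 1/c + 1/e + 1/g
Var_cc  = Var_co + 1/b + 1/d + 1/f + 1/h
Var_full= Var_co + 1/B + 1/D + 1/F + 1/H
```

`Var_co` is strictly smallest whenever any non-case cell is finite and
positive — the efficiency purchased by assuming S–E independence.

## Orientation of the S–E odds ratio

Two reciprocal conventions coexist for the "S–E odds ratio" and the
package keeps them explicit rather than letting them collide:

* **conventional**: `odds(S+|E+)/odds(S+|E−)` — what a logistic
  regression of S on E estimates as `exp(η₁)`, and what most readers
  mean by an odds ratio;
* **decomposition**: `(c+D)(e+F)/((a+B)(g+H))` — the factor for which
  `ICR_c/nc = ICR_co × seor` is an algebraic identity.  It is exactly
  the reciprocal of the conventional OR.

Under independence both equal 1 and the distinction is invisible; under
dependence only multiplication by the *decomposition* factor corrects
the case-only estimate (the case-only OR inflates by the conventional
association, so one divides by it — equivalently multiplies by its
reciprocal).  `seor_cnc`, `seor_control` and `fit_independence` take an
`orientation` argument defaulting to `"decomposition"`; the workflow
report stores both.  The independence *decision* (CI contains 1) is
orientation-invariant, since inversion swaps the CI bounds around 1.

`adjust_icr` itself is pure interval arithmetic on whatever two
estimates it is given: `point = icr_co × seor`, with either the
**bound-product** CI (multiply the CI bounds pairwise — reproducible by
hand from two printed estimates; the default) or the **lognormal-sum**
CI (log-scale SEs added in quadrature, which ignores the covariance of
the two estimates and is the statistically conventional choice when
both inputs come from the same sample).

## The five-step workflow

1. crude disease OR per unit of E;
2. crude disease OR per unit of S;
3. full-sample interaction `exp(β₃)` from `D ~ S + E + S:E`;
4. independence check: S–E OR in the **full** sample (never the
   controls — the control-population association is a different
   quantity; see the sensitivity analysis below), decided by the
   CI-contains-1 rule, optionally tightened by an ε-tolerance on the
   point estimate;
5. case-only estimate from `S ~ E` among cases; if step 4 found
   dependence, the adjusted estimate `ICR_co × seor(decomposition)` is
   the headline.  The adjusted value is computed and stored in *both*
   branches so a borderline decision can be inspected, but only
   headlined in the dependent branch.

Thresholded dichotomization (e.g. "exposure abnormal if > 1.4 µg/L") is
applied only with an explicit direction from the configuration; the
package never infers which side of a cutoff is abnormal.  Missing
values in used columns are removed by listwise deletion and counted.

**Continuous variables.**  A continuous exposure passes through every
logistic model unchanged (per-unit contrasts).  A continuous
susceptibility factor breaks the case-only model `logit P(S=1)` — that
likelihood is only defined for binary S — so the package refuses it by
default; passing `continuous_s="approx"` substitutes a least-squares
regression of S on E and reports `exp(slope)` under an explicit
`continuous-S approximation` flag.  This is an approximation the user
must opt into, not a silent estimator swap; the supported path is to
dichotomize S at a substantive threshold.

## Diagnostics

**Rare-disease sensitivity.**  The control-population S–E OR relates to
the full-sample one through

```
seor_control = seor_c/nc × [(1/p₀ − 1)(1/p₀ − RR_se)] /
               [(1/p₀ − RR_s)(1/p₀ − RR_e)]
```

with p₀ the baseline risk P(D|S−E−).  The factor is orientation-free
and tends to 1 as p₀ → 0, so substituting the control OR for the
full-sample OR is safe only for rare outcomes and modest single-factor
effects.  The symbol for the susceptibility relative risk in the source
literature for this formula is a residue of the gene–environment
setting; here it is the susceptibility-factor RR throughout.  The grid
helper defaults to p₀ ∈ {0.001, 0.005, 0.01, 0.03, 0.06} and
RR_s ∈ {1, 1.5, 2.5, 4}, the region where the distortion turns from
negligible to material.

**Stratification (subpopulation-dependence) bias.**  Mixing strata
whose S and E prevalence odds co-vary induces a marginal S–E
association even when S and E are independent within every stratum.
The confounding interaction ratio predicts the resulting
multiplicative bias, `CIR = r_SE·CV_S·CV_E + 1`, with analytic bounds
`U = √(υ_Sυ_E)(√(υ_Sυ_E)+1)² / ((√(υ_Sυ_E)+υ_S)(√(υ_Sυ_E)+υ_E))`,
`L = 1/U`, from the max/min odds ratios across strata.  An algebraic
point the implementation respects: when the within-stratum disease
model is shared, the mixture weights cancel exactly between the case
factor (ag/ce) and the non-case factor (DF/BH) of the full-sample
OR-basis ICR, so *pure margin mixing does not bias the full-sample
interaction estimate at all* — the bias lands on the case-only
estimator, which contains only the case factor.  `cir_empirical`
therefore reports the crude/stratified ratio of the **case-only**
estimates as the empirical CIR (stratification via stratum indicator
terms), and returns both full-sample fits alongside for reference.
Empirical r_SE and the CVs are stratum-size-weighted moments of the
per-stratum prevalence odds (unweighted variants available); these
operational definitions are this package's, since the closed form does
not prescribe them.

**Confounder-induced dependence.**  A shared cause C of S and E
likewise violates independence; the covariate-adjusted case-only model
`logit P(S=1) = γ₀′ + γ₁′E + γ₂′C` restores it when C is measured.  The
generator's confounder path exists to exercise exactly this repair.

## The synthetic-population generator

Per stratum, (S, E) is drawn from the unique 2×2 joint distribution
with margins (p_S, p_E) and conventional odds ratio `se_or` (Plackett
construction: the S⁺E⁺ cell solves a quadratic; the root keeping all
cells in [0,1] is taken), then D from
`logit P(D=1) = β₀ + β₁S + β₂E + β₃SE`.  The optional confounder draws
binary C first and shifts both margins by centred log-odds increments,
creating marginal S–E dependence with within-C independence.  A
Gaussian (S, E) variant with specified correlation serves the
continuous-variable code paths.  `expected_table` returns the
real-valued expected 2×4 counts n·P(S,E)·P(D|S,E) in closed form — the
exact oracle on which every identity is testable without sampling
noise.

Defaults (the generator's study conditions, fixed once):
`n = 20 000`, `p_S = p_E = 0.3`, `se_or = 1`, `β₀ = −5.5`
(baseline risk ≈ 0.4%, overall prevalence ≈ 0.8%), `β₁ = β₂ = ln 2`,
`β₃ = 0`, seed 20220929.  The rare-outcome baseline keeps the
risk-scale and odds-scale interaction contrasts within ~2% of each
other, which is what makes "the case-only estimator recovers exp(β₃)"
a meaningful statement: under independence `ICR_co` consistently
estimates the *RR-basis* full-sample ICR, and only in the rare-outcome
regime does that coincide with `exp(β₃)`.  The first-order RR/OR gap
of the full-sample ICR is `p₀₀ + p₁₁ − p₁₀ − p₀₁` in the stratum
risks, which is also why rare-disease agreement tests use tables and
baselines where that bound is below the stated tolerance.

What the generator emulates: a cross-sectional population with binary
or continuous S and E, controllable S–E association, stratification
and a single binary confounder.  What it does not: survey weights and
complex sampling, measurement error in S or E, missing-data
mechanisms, time-to-event outcomes.  Passing tests therefore
demonstrate the estimators' algebra and sampling behaviour under clean
conditions, not robustness to the messiness of real survey data.

## Monte-Carlo verification and its power

`recovery_experiment` redraws the population, collapses each replicate
to its 2×4 table and evaluates the estimators in closed form — on
binary saturated data these equal the logistic MLEs exactly (the
oracle-equivalence tests pin this to 1e-8), so the shortcut changes
nothing but runtime.  Summaries are on the log scale: mean log
estimate, bias, empirical SD, Monte-Carlo SE of the mean, mean Wald SE
and CI coverage.

One power consideration is documented because it shapes a test: under
the rare-outcome defaults the true variance excess of the full-sample
estimator over the case-only one is the non-case reciprocal sum
(≈ 0.0012 here) against a case-only variance of ≈ 0.10 — about 1%.
An empirical-SD comparison over R replicates resolves this at
`SD_X·√R / (2·SD_A)` Monte-Carlo SEs (A the case-only log estimate, X
the independent non-case factor), ≈ 0.054·√R: roughly 0.8 SE at
R = 200 (a coin flip) and 3.8 SE at R = 5000.  The efficiency claim is
therefore asserted two ways: the per-replicate Wald ordering (strict
for every table, the asymptotic prediction itself) and the empirical
SD ordering over 5000 paired replicates.  Problem sizes in the test
suite (n per replicate, replicate counts, table magnitudes) are chosen
so that each asserted effect stands ≥3 Monte-Carlo SEs above its
sampling noise wherever a stochastic comparison is made.

## Numerical choices

* CIs for closed-form ratio estimators are log-Wald with variance =
  the sum of reciprocal contributing cells (margins for the full-sample
  S–E OR); this matches the saturated-model Wald variances exactly on
  the OR scale.  The RR-basis multiplicative ICR shares cells between
  numerator and denominator, so it carries no closed-form CI — a
  seeded multinomial bootstrap (percentile, default 2000 resamples) is
  offered instead.  The OR-basis multiplicative ICR *does* carry the
  exact eight-cell Wald CI.
* Zero cells: optional Haldane–Anscombe +0.5 correction, off by
  default, always flagged in the output; zero numerators yield a
  flagged point estimate of 0 rather than an error where the estimand
  remains defined.
* Expected-value control sampling rounds half away from zero and warns
  on non-integer p·count; `sample_case_control_exact` keeps real-valued
  controls for analytic work.
* Logistic fits: statsmodels Newton with tolerance 1e-12; coefficients
  with |log-odds| > 15 are flagged as possible separation (nothing is
  penalized silently); non-convergence raises.
* Internal values are full precision; presentation rounds to 2
  decimals.
* Reports serialize with sorted keys and no timestamps, so identical
  inputs give byte-identical files; wall-clock times live only in the
  separate run log.

## Known limitations

* The case-only contrast is multiplicative only; the additive RERI is
  computed for full-sample tables but has no case-only counterpart.
* No survey weights, no exact (conditional) small-sample CIs, no
  penalized/Firth fits, no profile-likelihood intervals.
* The continuous-S case-only path is an explicit approximation (see
  above), not a fitted probability model.
* The CIR closed form is a first-order approximation in the odds
  dispersion; for widely spread strata (CV ≳ 0.7) it visibly
  underestimates the exact mixing odds ratio, which is why empirical
  checks use moderate dispersion.
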