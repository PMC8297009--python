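# Methods

## The study design this package implements

Structural models of psychopathology summarize comorbidity among disorder
symptoms with a small number of latent factors. The central question here
is whether such models — in particular the bifactor family with a general
*p*-factor — remain applicable and interpretable *within* subgroups of a
population, not only for the population as a whole. The package
implements a single-dataset simulation design that answers this by
construction:

1. generate a large population (default n = 100,000) of 11 continuous
   symptom-count variables whose correlation structure is implied by a
   published revised-bifactor solution, with positively skewed marginals,
   plus four IQ subscale composites with prescribed factor correlations;
2. fit four structural models to the full sample: correlated factors (A),
   full bifactor with correlated specifics (B), revised bifactor (C,
   the generating model) and single factor (D);
3. derive total-sample factor scores from the revised-bifactor fit, cut
   the sample into thirds on each symptom variable and on the Ext, Int
   and *p* scores, and form 63 overlapping subgroups (27 externalising,
   27 internalising, 9 thought-disorder variants);
4. refit all four models inside every subgroup (252 attempts), keep only
   solutions passing an admissibility and goodness-of-fit screen, and
5. compare loadings, cross-derivation factor-score correlations and IQ
   correlates between each passing subgroup and the total sample.

## Generating model and parameters

The revised bifactor model has a general factor *p* loading all 11
indicators and specific Externalising (alcohol, cannabis, hard drugs,
tobacco, conduct disorder) and Internalising (depression, GAD, fears)
factors, with the thought-disorder indicators (OCD, mania, schizophrenia)
loading on *p* only. *p* is orthogonal to Ext and Int; Ext~Int is free.
All factors have unit variance, so the packaged loading tables
(`pfactorlab/data/*.csv`) are used on the standardized metric directly
and residual variances are completed as one minus each indicator's
communality; the implied covariance Σ = ΛΦΛᵀ + Θ is then a correlation
matrix. Two parameter sets are shipped: the original empirical solution
(`caspi`, Ext~Int = −.471) — the default generating set — and the
solution refitted to the simulated population (`simdata`,
Ext~Int = −.387), which is the set whose implied covariance reproduces
the published full-sample fit indices of the misspecified models.

## Synthetic data

Marginal skew is induced with the Fleishman power polynomial
Y = a + bZ + cZ² + dZ³ applied to standard normal variates, with
coefficients solved numerically from the target (skewness, excess
kurtosis) pair. Defaults: skewness 2.0 for every symptom variable (the
level typical of symptom-count distributions in general-population data)
and excess kurtosis 7.0 — the kurtosis of a skew-2 count-like
distribution is not separately prescribed by the design, so a value
comfortably inside the polynomial's feasible region was fixed once. An
optional jitter draws per-variable skew targets from N(2.0, 0.35²)
truncated to the feasible region, mimicking realized between-variable
skew heterogeneity.

Because the polynomial transform attenuates correlations, pre-transform
correlations are corrected by solving the cubic relation between pre- and
post-transform correlation per variable pair (the Vale–Maurelli step), so
the post-transform correlation matrix converges to the model-implied one.
A `correct_intermediate=False` mode skips the correction; refitting the
generating model to such data recovers systematically attenuated
loadings, which reproduces the direction of the discrepancy between the
original and refitted generating parameters and suggests the original
dataset was generated without the correction.

The latent factor draws are retained. Each IQ covariate is a linear
combination of the true (p, Ext, Int) draws plus independent normal
noise, with weights w = Φ⁻¹r solved from the target correlation vector r
and latent correlation matrix Φ, then rescaled to mean 100, SD 15.
Building covariates from true latents (rather than estimated scores)
matches the design's definition of the targets as factor-level
associations.

What the generator does *not* emulate: ordinal or zero-inflated symptom
counts, item-level structure beneath the 11 disorder categories, missing
data, and sampling variability of the generating parameters themselves.
Passing tests therefore demonstrate internal consistency of the
estimation pipeline under the stated population model, not robustness to
those features of real data.

## Estimation

Models are fitted to the sample Pearson correlation matrix by maximum
likelihood, minimizing F = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − 11 over free
loadings, free factor correlations and residual variances (unit-variance
identification). The optimizer is a quasi-Newton pass (L-BFGS-B with
analytic gradient) followed by Fisher scoring with a Levenberg–Marquardt
ridge; outside the positive-definite region the objective switches to a
smooth eigenvalue-shortfall penalty so line searches are pushed back
toward feasibility rather than hitting an infinite barrier. Gradient
tolerance 1e−7, at most 500 iterations per stage; a fit counts as
converged when the gradient infinity-norm falls below 1e−4. Residual
variances and factor correlations are deliberately unconstrained:
Heywood cases and non-positive-definite latent covariances are diagnosed
after the fit. A solution running down an unbounded Heywood ridge
(standardized residual variance below −1) is flagged non-converged
without further polishing — no finite optimum exists there.

Factor sign indeterminacy is resolved by flipping any factor whose
loading sum is negative, making output deterministic.

With raw data available, the empirical fourth-moment matrix Γ of vech(S)
yields the mean-scaled (Satorra–Bentler) chi-square — the naive statistic
divided by c = tr(UΓ)/df with U the residual weight operator — and
sandwich standard errors. This is the standard "MLR-like" robustness
correction for skewed data; the mean-and-variance-adjusted variant used
by some software differs negligibly at these sample sizes and is not
implemented. Treating the correlation matrix as a covariance matrix when
computing standard errors follows common software practice; the
admissibility screen depends on z-ratios only through the α = .05
threshold (configurable), so this approximation is immaterial to the
verdicts.

The chi-square multiplier is n, not n − 1, and RMSEA uses the df·n
denominator — both forced by exact-arithmetic checks against the
reference full-sample statistics.

## Admissibility and model utility

A solution is admissible when it converged, every free loading is
significant (two-sided α = .05 on robust z by default; the loading tables
this design descends from mark loadings at p < .01, and both α levels
can be requested), no standardized loading is negative after the sign
convention, no residual variance is negative, and both the implied and
the latent covariance matrices are positive definite (eigenvalue
threshold −1e−8 — one defensible operationalization of "no
non-positive-definite identification issues"). Model utility additionally
requires RMSEA < .05, CFI > .95 and TLI > .95, all strict. CFI/TLI use
the independence baseline (closed form −n ln|R|, df 55), with a scaled
baseline when robust statistics are in use. SRMR averages squared
correlation-metric residuals over all 66 unique elements, diagonal
included (the common software default; the quantity is not otherwise
pinned down). The 90% RMSEA interval inverts the noncentral chi-square
distribution in its noncentrality parameter.

## Factor scores and subgroups

Scores use the regression (Thomson) estimator ΦΛᵀΣ⁻¹z — the usual
software default; the scoring method is not otherwise prescribed, and
Bartlett scores are available for sensitivity analysis. Scoring subgroup
members with a total-sample fit applies the total-sample weights and
standardization to their raw data; nothing is refitted. The *p* score is
affinely rescaled to mean 100, SD 15 (total-sample scores on the full
sample, subgroup scores within the subgroup); every reported correlation
is invariant to this rescaling, so the choice of standardization sample
is cosmetic.

Tertiles are cut at the full-sample 1/3 and 2/3 empirical quantiles,
coded 1 = upper, 2 = middle, 3 = lower, with ties going to the higher
category (measure-zero for continuous simulated data). A subject belongs
to an externalising variant a(ext)-b(ext)-c when at least one of the five
externalising disorders lies in symptom third a, the Ext score in third
b, and the *p* score in third c; internalising variants are analogous;
thought-disorder variants a(tht)-X-c have no factor condition because the
scoring model has no thought-disorder factor. The "at least one disorder"
rule makes subgroups overlap by design.

## Reported scales and reproducibility

A study run is fully determined by its `StudyConfig` (seed included); two
runs with the same config produce identical tables. The headline profile
is n = 100,000; the test suite exercises the full pipeline at that scale
once and uses 2,000–30,000 subjects elsewhere, sizes at which every
property under test is already stable. The count of subgroups passing the
screen is a property of each random dataset: the single-dataset reference
value (8 of 63) is carried in the report for comparison but never
asserted, and regenerated datasets typically pass more subgroups —
partly because this generator's corrected correlations preserve the
stronger original loadings. What is stable across datasets is the
qualitative pattern: every passing subgroup fits the correlated factors
model, the full bifactor never passes (its thought-disorder specific
factor is subsumed by *p*, leaving an inadmissible solution), the
revised bifactor passes a subset dominated by matching-thirds
thought-disorder variants, and the single-factor model almost never
passes.

## Known limitations

* Exact numeric replication of the original frozen dataset is impossible
  by construction: it was a single unseeded draw under an unstated skew
  transform and kurtosis.
* Robust statistics are mean-scaled only; loading significance in very
  small subgroups (a few hundred subjects) leans on asymptotic z-ratios.
* Subgroup fits in tiny or highly restricted subgroups can yield
  singular sample correlation matrices; these are recorded as errors and
  excluded, never fatal.
* The package does not implement higher-order factor models, ordinal
  (threshold) estimation, missing-data ML, or Monte-Carlo replication
  across many datasets.
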