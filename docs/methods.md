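# Methods

## Model and analysis scheme

The data model is a balanced two-factor layout with a random subject term:

```
value(subject s in group g, condition t, measure j)
    = beta_t + Delta_a(g) + P_{s,j} + eps_{s,t,j}
```

with fixed condition offsets `beta_t`, an optional fixed group offset
`Delta_a(g)`, a person effect `P ~ N(0, sigma_p^2)` drawn once per subject
and measure (shared across the `k` conditions), and i.i.d. error
`eps ~ N(0, sigma_e^2)` per cell. Under the null hypothesis all group
offsets are equal, so between-group differences arise only from subject
sampling and noise.

The MANOVA decomposition tests the group factor: `H` is the between-group
SSCP of group mean vectors about the grand mean (every subject x condition
observation counted once, `df_h = G - 1`), `E` the residual SSCP about the
group x condition cell means (`df_e = N_obs - G*k`). Each subject's
repeated conditions are treated as independent observations — the
repeated-measures covariance structure is deliberately not modelled,
because the resampling statistics are calibrated against Monte Carlo nulls
generated and analyzed by the *identical* scheme, so any misspecification
common to both sides cancels. Person effects therefore live partly in `H`
(through group-mean sampling noise) and partly in `E`; this is exactly the
confounding the F-ratio machinery is designed to resolve by the variance
channel rather than by the error-term enhancement of the classical mixed
test.

Multivariate F values follow the three standard conventions on the
eigenvalues `c_1 >= ... >= c_s` of `H E^{-1}` (Hotelling–Lawley mean root,
Pillai trace, Roy largest root), scaled by `df_e/df_h`. With two groups
`H` has rank one and the three coincide exactly.

## Resampling and the ratio statistics

`resample_f` draws, for each of `m` splittings, `round(p * n_g)` subjects
per group without replacement (round-half-to-even; independent draws per
splitting; subsets sorted so identical subject sets give bitwise-identical
F), keeps all their conditions, and recomputes the multivariate F plus
each measure's univariate F on the same subsets. The normalized ratio is
`R = sigma^2(F) / (4 <F>^2)`, chosen so that the theoretical null
expectation is `1/(2 df_k) + 1/(2 df_ek)` and the inversion
`nu = sqrt(max(0, 2 df_k (R - 1/(2 df_ek))))` returns 1 for a pure random
effect.

**Known calibration limitation.** The subset variance is a delete-d
jackknife estimate *up to a factor*: subsets of the same dataset overlap
(with `p = 2/3` any two share about two thirds of their subjects), so the
between-subset variance underestimates the true sampling variance of F.
A conditional-variance analysis for the rank-one group contrast gives the
deflation as a function of `beta = (1-p)/p`; at the default `p = 2/3`,
measurement and model agree on a factor near 0.73, i.e. a null mean of
`R` near 0.37 rather than the asymptotic 0.50, and a mean inverted `nu`
near 0.8 rather than 1. No analytic correction is applied: every observed
statistic is compared only against null deviates generated by the
identical procedure with identical `(m, p, n)`, so the factor cancels in
all inference (type-I calibration of the Monte Carlo p-value is exact by
construction, and the test suite verifies it within binomial bounds). The
raw `nu` point estimate should accordingly be read as a relative, not an
absolute, effect-size indicator at moderate `p`.

### Eigenvalue contributions

The recombination of univariate F values into eigen-terms needs a
contribution matrix `k_i^j` with `sum_j k_i^j F_j = c_i * df_e/df_h`. The
construction used here attributes each eigenvalue to measures
proportionally to the squared loadings of its `H E^{-1}` eigenvector, then
rescales so the identity holds exactly against the per-measure univariate
F values. Design rationale:

* for genuinely uncorrelated measures (diagonal `H`, `E`) it reduces to a
  selection matrix — each eigenvalue claimed wholly by one measure;
* under the null it keeps the recombined series statistically close to the
  multivariate F, which is what pins the null expectation of `teststat1R`
  at 1. A variant that additionally weights by the diagonal share of
  `H E^{-1}` was evaluated and rejected: its weights concentrate on
  measures whose full-sample F is randomly large, inflating the null mean
  of `teststat1R` to ~1.4 (a selection effect on noise).
* Contributions are computed once on the full-sample decomposition and
  held fixed across splittings; per-splitting eigenvector tracking is both
  unstable for small subsets and degenerate (it reconstructs the subset's
  own multivariate F exactly, collapsing `teststat1R` to the constant 1).

Residual bias: with `n = 3` measures and `df_e = 112` the null mean of
`teststat1R` measures ≈ 0.975 rather than 1.000 — an `O(n/df_e)` effect of
comparing a fixed linear recombination against the adaptive generalized
eigenvalue (the latter's relative subsampling variance is slightly
inflated by the Wishart noise of `E^{-1}`). Both tails of the statistic
should therefore be calibrated against its own Monte Carlo null rather
than against the asymptotic value 1; the package always does so.

The direction in which `teststat1R` leaves 1 under an alternative depends
on the correlation structure: for independent simulated measures with a
fixed effect on one of them, numerator and denominator are suppressed
almost equally and the statistic moves slightly *below* 1; pronounced
upward deviations require between-measure structure. Inference should use
two-sided Monte Carlo quantiles.

### Effective degrees of freedom

Pooled variances use the Welch–Satterthwaite form
`(sum sigma_i^2)^2 / sum(sigma_i^4 / df_i)`, which spans
`[min df, sum df]` — minimal when one term dominates, maximal for equal
contributions. (The simpler unsquared ratio is identically 1 whenever all
`df_i = 1` and cannot express intermediate values, so it is not usable
here.)

## Monte Carlo nulls, quantiles, p-values

`build_null_distribution` runs `L` independent simulate → resample →
statistic evaluations under the null generator (equal group effects),
fully reproducible from a single seed via spawned `SeedSequence` streams.
Quantiles follow the rank rule (the `ceil(P*L)`-th smallest deviate; low
tail is the rejection side for the ratio statistics), and p-values use the
add-one rule `(r+1)/(L+1)` with resolution floor `1/(L+1)`. For
statistics whose null level drifts with the effective degrees of freedom,
`quantile_vs_dfeff` bins replicates by `df_eff` (by distinct value when
there are few levels, otherwise equal-count bins) and fits
`quantile_P = a_P + b_P * df_eff`; `p_value` can then level-adjust the
null population to the observed `df_eff` along the fitted slope.

Defaults follow the canonical design they emulate: `L = 100`, `m = 30`,
`p = 2/3`, `k = 4` conditions with offsets `{0, 1, 2, 3}`, two groups of
15 subjects, `sigma_p = sigma_e = 1`. The offset magnitudes are
irrelevant to the group test (they are fixed and cancel in between-group
contrasts; a regression test asserts the null deviates are invariant
under offset changes); they are kept to mimic realistic state structure.
The generator accepts any zero-mean unit-variance deviate sampler, since
the Monte Carlo calibration argument does not rely on normality.

## Classical comparison

`classical_mixed_f` is the reference mixed-model test: the group effect on
one measure tested against the subject-within-group mean square
(`df = (G-1, N_subjects - G)`), computed in closed form on the balanced
layout (equivalent to one-way ANOVA on per-subject condition means). The
comparison study (`compare_with_classical`) pits its tail probability
against the F-ratio Monte Carlo p-value on many simulated datasets and
summarizes the sign asymmetry of `ΔP = P_classical - P_fratio`.

Under this Gaussian generative model the classical p-value is
stochastically *smaller* than the resampling p-value whenever a fixed
effect is truly present: both probabilities are monotone in the same
group-mean contrast, and the Monte Carlo route adds resampling noise
(`m` finite) plus the `1/(L+1)` floor. The comparison machinery is
provided for exactly this kind of head-to-head audit; a sensitivity
advantage for the resampling test should not be expected in the pure
Gaussian setting, and claims of one should be checked against the model
and effect sizes at hand.

## Hypothesis weighting and discriminant

Weights follow the posterior-odds algebra with a flat prior
(`c = 0.5`) and a common `P[B|H1] = c2` across alternatives: the ratio of
likelihood ratios of two nested alternatives is `pi_anchor / pi_other`,
directed so the *less* significant solution receives the *smaller* weight
(consistent with the worked three-measure example, where the 90% solution
enters at 0.47–0.48 against the anchored 95% solution). For
probabilities that are not small, the correction factor
`(1 - pi_other)/(1 - pi_anchor)` — the posterior-odds-consistent finite-pi
adjustment — is applied by default; it gives 0.4737 for (0.05, 0.10),
i.e. 0.47 at two decimals, 0.48 within rounding of the coarser quantile
probabilities real analyses produce. `drop_threshold` (default 0.05)
zeroes near-vanishing weights, dropping the measure.

The discriminant standardizes each retained measure (so weights act on
comparable scales), multiplies by its weight, and computes the two-class
Fisher axis `w = S_w^{-1}(mu_1 - mu_2)`; subjects are classified by the
nearer group mean on the axis, with resubstitution accuracy by default
and leave-one-out behind a flag (the choice matters: resubstitution is
optimistically biased, and permutation tests in the suite use
leave-one-out). Note that Fisher classification is invariant to any
*nonzero* diagonal rescaling of the inputs — fractional weights change
the axis coordinates (and hence plots and reported loadings) but not the
resubstitution predictions; the operative act of the weighting scheme on
classification is thresholding weak measures to zero, which reduces the
dimension and does change the fitted axis.

## What the synthetic generator does and does not emulate

It reproduces the design (group sizes, conditions, variance components,
fixed offsets) and the exchangeability structure the tests rely on. It
does not emulate serial correlation within recording sessions, unequal
group variances, non-Gaussian heavy tails (unless a custom sampler is
supplied), or correlated person effects across measures
(`between_measure_corr` correlates the *errors* only). Passing tests
therefore demonstrate internal calibration of the machinery under the
stated model, not robustness of the method on real recordings.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
canonical design (30 subjects x 4 conditions) with 100–500 Monte Carlo
replicates per check and `L = 100–500` null deviates, completing in a few
minutes on one core; larger `L` sharpens the p-value resolution floor
linearly at linear cost.
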