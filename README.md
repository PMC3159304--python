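# fratio

Resampling **F-ratio tests** for separating fixed from random effects in
(M)ANOVA, with **Bayesian hypothesis weighting** for building optimally
weighted feature vectors — the statistical back end for comparative studies
of signal-derived measures (EEG band powers, fractal dimension estimates,
and similar biomarkers) across subject groups.

## The problem

In a typical study design, two groups of subjects are each measured under
`k` conditions, and every measurement yields `n` numeric measures. A
classical MANOVA F-test of the group effect answers "do the groups differ
in *this sample*?" — but the subjects are a random draw from a population,
so part of any apparent group effect is sample-specific. The classical
mixed-model remedy tests the group effect against an error term enhanced by
the person-effect variance, which costs sensitivity.

The F-ratio approach attacks the problem through the *variance* of the F
statistic instead of its level. Deleting a random fraction of subjects and
recomputing F many times (a delete-d jackknife with `m` splittings keeping
a fraction `p` of each group) gives

```
sigma^2(F) = 1/(m-1) * sum_j (F_j - <F>)^2 ,   <F> = 1/m * sum_j F_j ,
```

and the normalized ratio `R = sigma^2(F) / (4 <F>^2)`. A *fixed* group
effect raises F but contributes nothing to its sample-to-sample variation,
so R falls below its pure-random-effect expectation
`1/(2 df_k) + 1/(2 df_ek)`; equivalently the ratio
`nu = ((Δpa)^2 + (Δe)^2) / h^2` of the random part of the effect term to
the whole drops below 1. Because the null distribution of R has no closed
form, it is generated by Monte Carlo: `L` synthetic datasets drawn from the
matched random-effects model, each pushed through the identical resampling
pipeline. Four statistics are provided:

* `teststat0` — `sum_i sigma^2(F_i) / (4 (sum_i <F_i>)^2)` over independent
  measures,
* `teststat1` — the eigenvalue-weighted multivariate form, built from the
  contributions `k_i^j` of each univariate F to the eigenvalues of
  `H E^-1` under a chosen stattype (Hotelling / Pillai / Roy),
* `teststat1R` — `teststat1` normalized by the multivariate ratio, with
  null expectation 1,
* `teststat1M` — the incremental form for testing one candidate measure
  against `k` already-accepted ones, with Welch–Satterthwaite effective
  degrees of freedom for the pooled variances.

Test outcomes at significance probabilities `pi_i` are then converted into
inclusion weights by Bayes' theorem: the most significant feature
combination is anchored at weight 1, and a less significant nested
alternative enters with the ratio of likelihood ratios
`pi_anchor / pi_other` (finite-`pi` corrected:
`pi_anchor (1 - pi_other) / (pi_other (1 - pi_anchor))`). Weights near
zero drop the measure, shrinking the feature vector; the result feeds a
two-class Fisher discriminant.

## Worked example

Thirty subjects (15 per group), four conditions, three measures; a fixed
group effect of 1.2 on `x1` and `x2`, `x3` pure noise:

```python
import fratio as fr

base = fr.simulate_dataset(fr.SimulationParams(n_measures=3), seed=7)
data = base.data.copy()
data[15:, :, :2] += 1.2           # fixed group effect on x1, x2
observed = fr.FeatureDataset(base.subjects, base.groups, base.conditions,
                             base.measures, data)

summary = fr.resample_f(observed, m=30, p=2/3, stattype="hotelling", seed=1)
print(f"multivariate <F> = {summary.f_mean:.3f}")
print(f"ratio R = sigma^2(F)/(4<F>^2) = {summary.ratio:.4f}")

nulldist = fr.build_null_distribution(
    fr.SimulationParams(n_measures=3), statistic="ratio",
    m=30, p=2/3, L=200, seed=2)
print(f"Monte Carlo p-value = {fr.p_value(nulldist, summary.ratio):.4f}")

weights = fr.build_feature_weights([
    fr.HypothesisSpec(features=fr.MeasureSubset(("x1", "x2")), pi=0.05),
    fr.HypothesisSpec(features=fr.MeasureSubset(("x1", "x2", "x3")), pi=0.10),
])
print("weights:", {k: round(v, 2) for k, v in weights.weights.items()})
result = fr.weighted_discriminant(observed, weights, "c1")
print(f"discriminant accuracy = {result.accuracy:.3f}")
```

prints

```
multivariate <F> = 77.369
ratio R = sigma^2(F)/(4<F>^2) = 0.0126
Monte Carlo p-value = 0.0050
weights: {'x1': 1.0, 'x2': 1.0, 'x3': 0.47}
discriminant accuracy = 0.833
```

The observed ratio (0.0126) sits far below the null population of ratios —
only 0.5% of random-effect simulations produce one as small — so the group
difference is a fixed effect, not a sampling artifact. The 90% solution's
extra measure `x3` enters the feature vector at weight 0.47 relative to the
anchored 95% solution, and the weighted discriminant separates the groups
at 83% resubstitution accuracy.

The same pipeline is available from the shell:

```sh
fratio simulate --n-measures 3 --group-effect 1.2 --seed 7 -o table.csv
fratio null --statistic ratio --n-measures 3 -L 200 --seed 2 -o null.json
fratio test table.csv --null-dist null.json --seed 1 -o report.json
fratio weight --pi 0.05 --features x1,x2 --pi 0.1 --features x1,x2,x3 -o w.json
fratio discriminate table.csv --weights w.json --condition c1
```

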