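"""Delete-d jackknife resampling of F and the F-ratio test statistics.

The core quantity is the subsampling variance of an F value: ``m`` random
splittings each keep a fraction ``p`` of the subjects per group (all their
conditions), the F value is recomputed on every subset, and

    sigma^2(F) = 1/(m-1) sum_j (F_j - <F>)^2,      <F> = 1/m sum_j F_j.

A fixed group effect contributes to F but not to its sample-to-sample
variation, so the normalized ratio

    R = sigma^2(F) / (4 <F>^2)

falls below its pure-random-effect expectation 1/(2 df_k) + 1/(2 df_ek)
when a fixed effect is present.  Four test statistics built from these
ratios (a plain sum over measures, an eigenvalue-weighted multivariate
form, its null-normalized version with expectation 1, and an incremental
form for adding a candidate measure) are implemented here; their null
distributions are Monte Carlo generated in :mod:`fratio.null`.

The subsampling estimate of sigma^2(F) carries an unspecified inflation
factor that depends on (m, p, sample size).  It is not corrected
analytically: observed statistics are only ever compared against null
deviates produced by the identical resampling procedure with identical
(m, p, n), so the factor cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import FeatureDataset
from .manova import (
    STATTYPES,
    EffectDecomposition,
    _eigen,
    _f_from_eigenvalues,
    _sscp_arrays,
)

__all__ = [
    "ResampleSummary",
    "TestStatResult",
    "NuEstimate",
    "resample_f",
    "teststat0",
    "teststat1",
    "teststat1R",
    "teststat1M",
    "effective_df",
    "estimate_nu",
]


class DegenerateStatisticError(ZeroDivisionError):
    """A denominator of an F-ratio statistic vanished."""


@dataclass(frozen=True)
class ResampleSummary:
    """The m subset F values and their jackknife summary for one statistic."""

    f_values: np.ndarray
    m: int
    p: float
    stattype: str
    seed: object = None
    per_measure: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fv = np.asarray(self.f_values, dtype=float)
        object.__setattr__(self, "f_values", fv)
        if len(fv) != self.m or self.m < 2:
            raise ValueError("need m >= 2 subset F values")

    @property
    def f_mean(self) -> float:
        return float(self.f_values.mean())

    @property
    def f_var(self) -> float:
        return float(self.f_values.var(ddof=1))

    @property
    def ratio(self) -> float:
        """Normalized ratio R = sigma^2(F) / (4 <F>^2)."""
        mean = self.f_mean
        if mean == 0:
            raise DegenerateStatisticError("mean subset F is zero")
        return self.f_var / (4.0 * mean**2)

    def to_dict(self) -> dict:
        return {
            "f_values": self.f_values.tolist(),
            "f_mean": self.f_mean,
            "f_var": self.f_var,
            "ratio": self.ratio,
            "m": self.m,
            "p": self.p,
            "stattype": self.stattype,
            "seed": self.seed,
            "per_measure": {k: v.to_dict() for k, v in self.per_measure.items()},
        }


@dataclass(frozen=True)
class TestStatResult:
    name: str
    value: float
    df_eff: float
    components: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        comp = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.components.items()
        }
        return {"name": self.name, "value": self.value, "df_eff": self.df_eff,
                "components": comp}


@dataclass(frozen=True)
class NuEstimate:
    """Estimated ratio of the random part of the effect term to the whole.

    nu = 1 for a pure random effect; nu < 1 signals a fixed effect.
    """

    nu: float
    df_k: int
    df_ek: int


def _subset_sizes(dataset: FeatureDataset, p: float) -> dict:
    codes = dataset.group_codes()
    sizes = {}
    for g in range(len(dataset.group_labels)):
        n_g = int((codes == g).sum())
        r = round(p * n_g)  # round-half-to-even
        if r < 2:
            raise ValueError(
                f"subset fraction p={p} keeps only {r} subjects in group "
                f"{dataset.group_labels[g]!r}; need >= 2"
            )
        sizes[g] = r
    return sizes


def resample_f(
    dataset: FeatureDataset,
    m: int = 30,
    p: float = 2.0 / 3.0,
    stattype: str = "hotelling",
    seed: int | np.random.SeedSequence | None = None,
    per_measure: bool = True,
) -> ResampleSummary:
    """Jackknife-resample the multivariate F over m random splittings.

    Each splitting draws ``round(p * n_g)`` subjects per group without
    replacement (independently across splittings, the same count for every
    splitting), keeps all their conditions, and recomputes the group
    MANOVA F under ``stattype``.  When ``per_measure`` is set, the
    univariate ANOVA F of each measure is computed on the same subsets and
    returned as nested summaries.
    """
    if m < 2:
        raise ValueError("need m >= 2 splittings")
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if stattype not in STATTYPES:
        raise ValueError(f"unknown stattype {stattype!r}")
    sizes = _subset_sizes(dataset, p)
    if p == 1.0:
        warnings.warn(
            "p = 1 resamples the full sample every time; sigma^2(F) is degenerate"
        )
    codes = dataset.group_codes()
    n_groups = len(dataset.group_labels)
    subset_obs = sum(sizes.values()) * dataset.n_conditions
    if subset_obs - n_groups * dataset.n_conditions <= 0:
        raise ValueError("subsets leave no error degrees of freedom")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(m)

    X = dataset.data
    n = dataset.n_measures
    group_idx = [np.flatnonzero(codes == g) for g in range(n_groups)]

    f_multi = np.empty(m)
    f_uni = np.empty((m, n))
    sub_codes = np.concatenate(
        [np.full(sizes[g], g, dtype=np.intp) for g in range(n_groups)]
    )
    for j in range(m):
        rng = np.random.default_rng(children[j])
        take = np.concatenate(
            [np.sort(rng.choice(group_idx[g], size=sizes[g], replace=False))
             for g in range(n_groups)]
        )
        H, E, df_h, df_e = _sscp_arrays(X[take], sub_codes, n_groups)
        diag_h = np.diag(H)
        diag_e = np.diag(E)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_uni[j] = np.where(diag_e > 0, diag_h / diag_e * df_e / df_h, 0.0)
        if n == 1:
            f_multi[j] = f_uni[j, 0]
        else:
            vals, _ = _eigen(H, E)
            f_multi[j] = (
                _f_from_eigenvalues(vals, df_h, df_e, stattype) if len(vals) else 0.0
            )

    per: dict = {}
    if per_measure:
        per = {
            meas: ResampleSummary(
                f_values=f_uni[:, jm], m=m, p=p, stattype="univariate", seed=None
            )
            for jm, meas in enumerate(dataset.measures)
        }
    return ResampleSummary(
        f_values=f_multi,
        m=m,
        p=p,
        stattype=stattype,
        seed=getattr(ss, "entropy", None),
        per_measure=per,
    )


def effective_df(variances, dfs) -> float:
    """Welch-Satterthwaite effective degrees of freedom of pooled variances.

    ``(sum sigma_i^2)^2 / sum(sigma_i^4 / df_i)`` — minimal (the smallest
    df contribution) when one term dominates, maximal (``sum df_i``) for
    equal contributions.
    """
    v = np.asarray(variances, dtype=float)
    d = np.asarray(dfs, dtype=float)
    if np.any(v < 0) or np.any(d < 1):
        raise ValueError("variances must be >= 0 and dfs >= 1")
    if not np.any(v > 0):
        raise ValueError("effective df undefined for all-zero variances")
    return float(v.sum() ** 2 / np.sum(v**2 / d))


def _check_same_m(summaries) -> int:
    ms = {s.m for s in summaries}
    if len(ms) != 1:
        raise ValueError("all summaries must come from the same m splittings")
    return ms.pop()


def teststat0(per_measure: dict) -> TestStatResult:
    """Plain multivariate F-ratio statistic over independent measures.

    ``sum_i sigma^2(F_i) / (4 (sum_i <F_i>)^2)`` with the effective df of
    the pooled variances.  Small values indicate a systematic nonrandom
    deviation in at least one measure.
    """
    if not per_measure:
        raise ValueError("need at least one measure summary")
    summaries = list(per_measure.values())
    _check_same_m(summaries)
    variances = np.array([s.f_var for s in summaries])
    means = np.array([s.f_mean for s in summaries])
    denom = means.sum()
    if denom == 0:
        raise DegenerateStatisticError("sum of mean F values is zero")
    value = variances.sum() / (4.0 * denom**2)
    df_eff = effective_df(variances, np.ones(len(variances)))
    return TestStatResult(
        name="teststat0",
        value=float(value),
        df_eff=df_eff,
        components={"variances": variances, "means": means},
    )


def _eigen_weights(dec: EffectDecomposition, stattype: str) -> np.ndarray:
    """Per-eigenvalue weights omega_i with sum_i omega_i c_i df_e/df_h = F."""
    c = dec.eigenvalues
    s = dec.s
    if stattype == "hotelling":
        return np.full(s, 1.0 / s)
    if stattype == "pillai":
        v = np.sum(c / (1.0 + c))
        return (1.0 / (1.0 + c)) / (s - v)
    if stattype == "roy":
        w = np.zeros(s)
        w[0] = 1.0
        return w
    raise ValueError(f"unknown stattype {stattype!r}")


def _eigen_term_series(
    contributions: np.ndarray, per_measure: dict, dec: EffectDecomposition,
    stattype: str,
) -> np.ndarray:
    """Per-splitting eigen-term series g_i^{-1} sum_j k_ij F_j(t).

    Contributions are computed once on the full-sample decomposition and
    held fixed across splittings.  For the Hotelling stattype the constant
    eigenvalue weight collapses the terms into a single series, making the
    statistic identical to the rank-one form applied to the trace.
    """
    names = list(dec.measures)
    missing = [nm for nm in names if nm not in per_measure]
    if missing:
        raise ValueError(f"missing per-measure summaries for {missing}")
    _check_same_m([per_measure[nm] for nm in names])
    F = np.stack([per_measure[nm].f_values for nm in names], axis=1)  # (m, n)
    K = np.asarray(contributions, dtype=float)
    if K.shape != (dec.s, dec.n):
        raise ValueError(f"contributions shape {K.shape} != (s={dec.s}, n={dec.n})")
    omega = _eigen_weights(dec, stattype)
    terms = F @ K.T * omega  # (m, s)
    if stattype == "hotelling":
        terms = terms.sum(axis=1, keepdims=True)
    return terms


def teststat1(
    contributions: np.ndarray,
    per_measure: dict,
    dec: EffectDecomposition,
    stattype: str = "hotelling",
) -> TestStatResult:
    """Eigenvalue-weighted multivariate F-ratio statistic.

    The univariate per-splitting F values are recombined through the
    full-sample eigenvalue contributions ``k_ij`` and stattype weights;
    the statistic is the pooled variance of the eigen-terms over the
    squared sum of their means (with the factor 4 normalization).
    """
    terms = _eigen_term_series(contributions, per_measure, dec, stattype)
    variances = terms.var(axis=0, ddof=1)
    means = terms.mean(axis=0)
    denom = means.sum()
    if denom == 0:
        raise DegenerateStatisticError("sum of eigen-term means is zero")
    value = variances.sum() / (4.0 * denom**2)
    df_eff = effective_df(variances, np.ones(len(variances))) if np.any(
        variances > 0
    ) else 1.0
    return TestStatResult(
        name="teststat1",
        value=float(value),
        df_eff=df_eff,
        components={"variances": variances, "means": means},
    )


def teststat1R(
    multi: ResampleSummary,
    per_measure: dict,
    contributions: np.ndarray,
    dec: EffectDecomposition,
    stattype: str = "hotelling",
) -> TestStatResult:
    """Null-normalized multivariate statistic with expectation 1 under H0.

    The eigenvalue-weighted ratio is divided by the multivariate ratio
    ``sigma^2(F_multi)/(4 <F_multi>^2)`` computed on the same splittings.
    Significant deviations from 1 indicate a fixed effect in at least one
    measure or a between-measure effect.
    """
    if multi.f_var == 0:
        raise DegenerateStatisticError(
            "multivariate resampling variance is zero (p = 1?)"
        )
    t1 = teststat1(contributions, per_measure, dec, stattype)
    value = t1.value / multi.ratio
    return TestStatResult(
        name="teststat1R",
        value=float(value),
        df_eff=t1.df_eff,
        components={**t1.components, "multi_ratio": multi.ratio},
    )


def teststat1M(
    f_c: float,
    var_f_c: float,
    k: int,
    add: ResampleSummary,
    multi: ResampleSummary,
) -> TestStatResult:
    """Incremental statistic for adding one candidate measure.

    With ``k`` measures already carrying an effect of size ``F_c`` (and
    resampling variance ``var_f_c``), a candidate with summary ``add`` is
    tested through

        [k^2 var(F_c) + sigma^2(F_add)] / (4 (k F_c + <F_add>)^2)

    normalized by the multivariate ratio.  Unexpectedly high values
    indicate an additional systematic effect from the candidate.
    """
    if f_c <= 0:
        raise ValueError("carried-over F_c must be positive")
    if k < 1:
        raise ValueError("need k >= 1 carried measures")
    denom = k * f_c + add.f_mean
    if denom == 0:
        raise DegenerateStatisticError("k*F_c + <F_add> is zero")
    if multi.f_var == 0:
        raise DegenerateStatisticError("multivariate resampling variance is zero")
    num = (k**2 * var_f_c + add.f_var) / (4.0 * denom**2)
    value = num / multi.ratio
    df_eff = effective_df([k**2 * var_f_c, add.f_var], [k, 1])
    return TestStatResult(
        name="teststat1M",
        value=float(value),
        df_eff=df_eff,
        components={
            "f_c": f_c,
            "var_f_c": var_f_c,
            "k": k,
            "f_add_mean": add.f_mean,
            "f_add_var": add.f_var,
            "multi_ratio": multi.ratio,
        },
    )


def estimate_nu(ratio: float, df_k: int, df_ek: int) -> NuEstimate:
    """Invert the null expectation of the normalized ratio for nu.

    From ``E[R] = nu^2/(2 df_k) + 1/(2 df_ek)``:
    ``nu = sqrt(max(0, 2 df_k (R - 1/(2 df_ek))))``, clamped at zero.
    nu = 1 marks a pure random effect; lower values point to a
    non-negligible fixed effect.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    nu = float(np.sqrt(max(0.0, 2.0 * df_k * (ratio - 1.0 / (2.0 * df_ek)))))
    return NuEstimate(nu=nu, df_k=df_k, df_ek=df_ek)
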