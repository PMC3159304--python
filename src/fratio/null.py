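"""Monte Carlo null distributions, quantiles, p-values and the
classical-vs-resampling comparison study.

The null distribution of an F-ratio statistic has no tractable closed
form — it depends on (df_k, df_ek, number of measures, m, p, sample
size, stattype) — so it is generated empirically: L independent datasets
are simulated under the null hypothesis (no fixed group effect), each is
pushed through the identical resampling pipeline used for the observed
data, and the L statistic values form the reference population.  Small
observed values are the rejection side: a fixed effect suppresses the
sample-to-sample variation of F.

For the incremental statistic the null quantiles drift with the
effective degrees of freedom of the pooled variances; a linear fit
quantile_P = a_P + b_P * df_eff over df_eff bins lets quantiles (and
p-values) be read off at the df_eff of the observed sample instead of
waiting for replicates with matching df_eff to occur by chance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .data import FeatureDataset
from .manova import classical_mixed_f, decompose, eigen_contributions
from .simulate import SimulationParams, simulate_dataset
from .stats import ResampleSummary, resample_f, teststat0, teststat1, teststat1R

__all__ = [
    "NullDistribution",
    "ComparisonResult",
    "STATISTICS",
    "evaluate_statistic",
    "build_null_distribution",
    "empirical_quantile",
    "quantile_vs_dfeff",
    "p_value",
    "compare_with_classical",
]

STATISTICS = ("ratio", "teststat0", "teststat1", "teststat1R")


def evaluate_statistic(
    dataset: FeatureDataset,
    statistic: str,
    m: int = 30,
    p: float = 2.0 / 3.0,
    stattype: str = "hotelling",
    seed=None,
) -> tuple[float, float]:
    """Resample a dataset and evaluate one named statistic.

    Returns ``(value, df_eff)``; for the plain multivariate ratio df_eff
    is reported as 1.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    summary = resample_f(dataset, m=m, p=p, stattype=stattype, seed=seed)
    if statistic == "ratio":
        return summary.ratio, 1.0
    if statistic == "teststat0":
        res = teststat0(summary.per_measure)
        return res.value, res.df_eff
    dec = decompose(dataset)
    K = eigen_contributions(dec)
    if statistic == "teststat1":
        res = teststat1(K, summary.per_measure, dec, stattype)
    else:
        res = teststat1R(summary, summary.per_measure, K, dec, stattype)
    return res.value, res.df_eff


@dataclass(frozen=True)
class NullDistribution:
    """L Monte Carlo deviates of a statistic under the null hypothesis."""

    deviates: np.ndarray
    df_eff_values: np.ndarray
    statistic: str
    params: SimulationParams
    m: int
    p: float
    stattype: str
    seed: object = None
    fit: dict = field(default_factory=dict)  # P -> (a_P, b_P)

    def __post_init__(self) -> None:
        dv = np.asarray(self.deviates, dtype=float)
        object.__setattr__(self, "deviates", dv)
        object.__setattr__(
            self, "df_eff_values", np.asarray(self.df_eff_values, dtype=float)
        )
        if len(dv) < 20:
            raise ValueError("need L >= 20 null deviates")
        if np.any(dv < 0) or not np.all(np.isfinite(dv)):
            raise ValueError("null deviates must be finite and >= 0")

    @property
    def L(self) -> int:
        return len(self.deviates)

    def to_dict(self) -> dict:
        return {
            "deviates": self.deviates.tolist(),
            "df_eff_values": self.df_eff_values.tolist(),
            "statistic": self.statistic,
            "params": self.params.to_dict(),
            "m": self.m,
            "p": self.p,
            "stattype": self.stattype,
            "seed": self.seed,
            "fit": {str(k): list(v) for k, v in self.fit.items()},
        }


def build_null_distribution(
    params: SimulationParams,
    statistic: str = "ratio",
    m: int = 30,
    p: float = 2.0 / 3.0,
    stattype: str = "hotelling",
    L: int = 100,
    seed: int | np.random.SeedSequence | None = None,
) -> NullDistribution:
    """Generate L independent null deviates of the chosen statistic.

    The generator must satisfy the null hypothesis (equal group effects);
    each replicate simulates a fresh dataset and runs the identical
    resampling procedure that will be applied to the observed data.  A
    replicate that fails numerically is retried with a fresh sub-seed at
    most 3 times.
    """
    if len(set(params.group_effects)) != 1:
        raise ValueError("null generation requires equal group effects (H0)")
    if L < 20:
        raise ValueError("need L >= 20")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(L)
    deviates = np.empty(L)
    dfs = np.empty(L)
    for i in range(L):
        child = children[i]
        for attempt in range(4):
            try:
                data_seed, resample_seed = child.spawn(2)
                ds = simulate_dataset(params, seed=data_seed)
                deviates[i], dfs[i] = evaluate_statistic(
                    ds, statistic, m=m, p=p, stattype=stattype, seed=resample_seed
                )
                break
            except (ZeroDivisionError, np.linalg.LinAlgError):
                if attempt == 3:
                    raise
                child = child.spawn(1)[0]
    return NullDistribution(
        deviates=deviates,
        df_eff_values=dfs,
        statistic=statistic,
        params=params,
        m=m,
        p=p,
        stattype=stattype,
        seed=getattr(ss, "entropy", None),
    )


def empirical_quantile(nulldist: NullDistribution | np.ndarray, P: float) -> float:
    """Rank-order P-quantile: the ceil(P*L)-th smallest deviate."""
    if not 0 < P < 1:
        raise ValueError("P must lie in (0, 1)")
    dv = nulldist.deviates if isinstance(nulldist, NullDistribution) else np.asarray(
        nulldist, dtype=float
    )
    L = len(dv)
    rank = max(1, math.ceil(P * L))
    return float(np.sort(dv)[rank - 1])


def quantile_vs_dfeff(
    nulldist: NullDistribution, P: float, n_bins: int = 8
) -> tuple[float, float]:
    """Linear fit of the null P-quantile against effective df.

    Replicates are binned by df_eff (equal-count bins), the empirical
    P-quantile is taken per bin, and quantile_P = a_P + b_P * df_eff is
    least-squares fitted through the bin points.  The coefficients are
    cached on the distribution so :func:`p_value` can level-adjust
    deviates to an observed df_eff.
    """
    dfs = nulldist.df_eff_values
    if np.ptp(dfs) == 0:
        warnings.warn("all df_eff identical; slope is degenerate, returning b_P = 0")
        coeff = (empirical_quantile(nulldist, P), 0.0)
        nulldist.fit[P] = coeff
        return coeff
    uniq = np.unique(dfs)
    if len(uniq) <= n_bins:
        # few distinct df_eff levels: one bin per level keeps the per-bin
        # quantile exactly representative
        splits = [np.flatnonzero(dfs == u) for u in uniq]
    else:
        order = np.argsort(dfs, kind="stable")
        n_bins = min(n_bins, max(2, len(dfs) // 5))
        splits = np.array_split(order, n_bins)
    xs, ys = [], []
    for idx in splits:
        if len(idx) == 0:
            continue
        xs.append(float(dfs[idx].mean()))
        ys.append(empirical_quantile(nulldist.deviates[idx], P))
    b, a = np.polyfit(xs, ys, 1)
    coeff = (float(a), float(b))
    nulldist.fit[P] = coeff
    return coeff


def p_value(
    nulldist: NullDistribution,
    observed: float,
    df_eff: float | None = None,
) -> float:
    """Monte Carlo tail probability of a ratio as small or smaller.

    ``(r + 1) / (L + 1)`` with ``r`` the count of null deviates <= the
    observed value (the add-one rule avoids zero p-values; the resolution
    floor is ``1/(L+1)``).  When ``df_eff`` is given and a quantile fit
    exists, deviates are first level-adjusted to the observed df_eff along
    the fitted slope.
    """
    if not np.isfinite(observed):
        raise ValueError("observed statistic must be finite")
    dv = nulldist.deviates
    if df_eff is not None and nulldist.fit:
        # use the slope of the median-most fitted P
        P_ref = min(nulldist.fit, key=lambda q: abs(q - 0.5))
        _, b = nulldist.fit[P_ref]
        dv = dv + b * (df_eff - nulldist.df_eff_values)
    r = int(np.sum(dv <= observed))
    return (r + 1) / (nulldist.L + 1)


@dataclass(frozen=True)
class ComparisonResult:
    """Per-dataset probability differences between the two test families.

    ``delta_p[i] = P_classical - P_fratio`` for the i-th simulated
    dataset.  A symmetric distribution around zero means the tests are
    equivalent in sensitivity; an excess of positive differences means
    the resampling test assigns smaller chance probabilities to the same
    outcomes, i.e. is the more sensitive test.
    """

    delta_p: np.ndarray
    n_positive: int
    n_negative: int
    chi2: float
    p_sign: float

    def to_dict(self) -> dict:
        return {
            "delta_p": self.delta_p.tolist(),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "chi2": self.chi2,
            "p_sign": self.p_sign,
        }


def compare_with_classical(
    params: SimulationParams,
    n_datasets: int = 100,
    m: int = 30,
    p: float = 2.0 / 3.0,
    L: int = 100,
    measure: str | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> ComparisonResult:
    """Head-to-head comparison of the classical mixed test and the F-ratio test.

    For each of ``n_datasets`` datasets simulated from ``params`` (which
    may carry a fixed group effect), the univariate classical mixed-model
    tail probability and the Monte Carlo p-value of the resampling ratio
    are computed; the null reference population for the latter is
    generated once from the H0 version of ``params``.  Returns the per
    dataset differences and a one-degree-of-freedom sign test against a
    50/50 split.
    """
    if params.n_measures != 1:
        raise ValueError("the comparison study is defined for one measure")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    null_seed, data_seed = ss.spawn(2)
    nulldist = build_null_distribution(
        params.under_null(), statistic="ratio", m=m, p=p, L=L, seed=null_seed
    )
    children = data_seed.spawn(n_datasets)
    delta = np.empty(n_datasets)
    for i in range(n_datasets):
        sim_seed, resample_seed = children[i].spawn(2)
        ds = simulate_dataset(params, seed=sim_seed)
        meas = measure or ds.measures[0]
        _, p_classical = classical_mixed_f(ds, meas)
        value, _ = evaluate_statistic(ds, "ratio", m=m, p=p, seed=resample_seed)
        p_fr = p_value(nulldist, value)
        delta[i] = p_classical - p_fr
    n_pos = int(np.sum(delta > 0))
    n_neg = int(np.sum(delta < 0))
    n_eff = n_pos + n_neg
    if n_eff > 0:
        chi2 = (n_pos - n_neg) ** 2 / n_eff
        p_sign = float(sps.chi2.sf(chi2, 1))
    else:
        chi2, p_sign = 0.0, 1.0
    return ComparisonResult(
        delta_p=delta, n_positive=n_pos, n_negative=n_neg,
        chi2=float(chi2), p_sign=p_sign,
    )
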