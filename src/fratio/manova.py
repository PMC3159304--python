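"""Classical ANOVA/MANOVA machinery.

The group factor is the tested effect.  The hypothesis matrix ``H`` is the
between-group sums-of-squares-and-cross-products (SSCP) matrix of the
group mean vectors about the grand mean, with every subject x condition
observation counted once.  The error matrix ``E`` is the residual SSCP
about the group x condition cell means, so fixed condition offsets are
absorbed and per-subject (random) deviations remain in ``E``.  Repeated
conditions of a subject are treated as independent observations; the
repeated-measures covariance structure is deliberately not modelled,
matching the standard-package analysis scheme the resampling tests are
calibrated against.

Multivariate F statistics are formed from the eigenvalues ``c_i`` of
``H E^{-1}`` under the three usual conventions (Hotelling-Lawley trace,
Pillai trace, Roy largest root); for a rank-one hypothesis the three
coincide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats as sps

from .data import FeatureDataset

__all__ = [
    "EffectDecomposition",
    "ManovaF",
    "VarianceComponents",
    "STATTYPES",
    "decompose",
    "manova_f",
    "eigen_contributions",
    "estimate_variance_components",
    "classical_mixed_f",
]

logger = logging.getLogger(__name__)

STATTYPES = ("hotelling", "pillai", "roy")

#: relative eigenvalue cutoff defining the numerical rank s
RANK_RTOL = 1e-10
RANK_ATOL = 1e-12


class SingularErrorMatrix(np.linalg.LinAlgError):
    """E is singular: more observations or fewer measures are needed."""


class DegenerateEffectError(ValueError):
    """The effect SSCP has rank zero (no between-group variation)."""


@dataclass(frozen=True)
class EffectDecomposition:
    """H/E SSCP decomposition for one tested effect.

    ``eigenvalues`` holds the descending nonzero spectrum of ``H E^{-1}``
    (length ``s``); ``eigenvectors`` the matching generalized eigenvectors
    ``v_i`` with ``H v = c E v``, columns aligned with ``eigenvalues``.
    """

    H: np.ndarray = field(repr=False)
    E: np.ndarray = field(repr=False)
    df_h: int
    df_e: int
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray = field(repr=False)
    measures: tuple

    @property
    def s(self) -> int:
        return len(self.eigenvalues)

    @property
    def n(self) -> int:
        return self.H.shape[0]

    def univariate_f(self) -> np.ndarray:
        """Per-measure univariate ANOVA F: (H_jj / E_jj) * df_e / df_h.

        With uncorrelated errors the diagonal of H E^{-1} represents these
        individual F values on average, and the trace is their sum.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(np.diag(self.E) > 0, np.diag(self.H) / np.diag(self.E), 0.0)
        return d * self.df_e / self.df_h

    def to_dict(self) -> dict:
        return {
            "measures": list(self.measures),
            "H": self.H.tolist(),
            "E": self.E.tolist(),
            "df_h": self.df_h,
            "df_e": self.df_e,
            "eigenvalues": self.eigenvalues.tolist(),
        }


@dataclass(frozen=True)
class ManovaF:
    """A multivariate F value under one of the three stattype conventions."""

    stattype: str
    value: float
    df_h: int
    df_e: int


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments error and person-effect variances (clamped >= 0)."""

    sigma_e2: float
    sigma_p2: float


def _sscp_arrays(
    X: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Raw H/E computation on an (S, k, n) value array.

    Returns (H, E, df_h, df_e).  Kept separate from the dataset wrapper so
    the resampling loop can call it on index-selected arrays cheaply.
    """
    S, k, n = X.shape
    obs = X.reshape(S * k, n)
    grand = obs.mean(axis=0)

    H = np.zeros((n, n))
    E = obs.T @ obs
    for g in range(n_groups):
        Xg = X[codes == g]  # (S_g, k, n)
        Sg = Xg.shape[0]
        gmean = Xg.reshape(Sg * k, n).mean(axis=0) - grand
        H += Sg * k * np.outer(gmean, gmean)
        cell_means = Xg.mean(axis=0)  # (k, n)
        E -= Sg * np.einsum("kj,kl->jl", cell_means, cell_means)
    df_h = n_groups - 1
    df_e = S * k - n_groups * k
    # symmetrize against accumulation noise
    H = 0.5 * (H + H.T)
    E = 0.5 * (E + E.T)
    return H, E, df_h, df_e


def _eigen(H: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending nonzero generalized eigenpairs of H v = c E v."""
    try:
        vals, vecs = scipy.linalg.eigh(H, E)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise SingularErrorMatrix(
            "error SSCP matrix E is singular; add observations or drop measures"
        ) from exc
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    c1 = vals[0] if len(vals) else 0.0
    cutoff = RANK_RTOL * c1 if c1 > 0 else RANK_ATOL
    keep = vals > cutoff
    return vals[keep], vecs[:, keep]


def decompose(dataset: FeatureDataset, effect: str = "group") -> EffectDecomposition:
    """Decompose a dataset into H/E SSCP matrices for the group effect.

    Degrees of freedom: ``df_h = G - 1`` and ``df_e = N_obs - G*k`` with
    ``N_obs`` the number of subject x condition observations.
    """
    if effect != "group":
        raise ValueError(f"unsupported effect {effect!r}; only 'group' is defined")
    labels = dataset.group_labels
    if len(labels) < 2:
        raise ValueError("group decomposition needs at least 2 groups")
    H, E, df_h, df_e = _sscp_arrays(dataset.data, dataset.group_codes(), len(labels))
    if df_e <= 0:
        raise SingularErrorMatrix("no error degrees of freedom left")
    n = dataset.n_measures
    if np.allclose(H, 0.0, atol=RANK_ATOL):
        # identical group means: zero effect, s = 0, no eigenproblem to solve
        return EffectDecomposition(
            H=H, E=E, df_h=df_h, df_e=df_e,
            eigenvalues=np.empty(0), eigenvectors=np.empty((n, 0)),
            measures=dataset.measures,
        )
    vals, vecs = _eigen(H, E)
    # rank of H E^-1 cannot exceed df_h
    vals, vecs = vals[: min(len(vals), df_h, dataset.n_measures)], vecs
    return EffectDecomposition(
        H=H,
        E=E,
        df_h=df_h,
        df_e=df_e,
        eigenvalues=vals,
        eigenvectors=vecs[:, : len(vals)],
        measures=dataset.measures,
    )


def _f_from_eigenvalues(c: np.ndarray, df_h: int, df_e: int, stattype: str) -> float:
    s = len(c)
    ratio = df_e / df_h
    if stattype == "hotelling":
        return float(c.sum() / s * ratio)
    if stattype == "pillai":
        v = np.sum(c / (1.0 + c))
        return float(v / (s - v) * ratio)
    if stattype == "roy":
        return float(c[0] * ratio)
    raise ValueError(f"unknown stattype {stattype!r}; choose from {STATTYPES}")


def manova_f(dec: EffectDecomposition, stattype: str = "hotelling") -> ManovaF:
    """Multivariate F under the requested stattype.

    For ``s = 1`` all three conventions return the identical value; in the
    univariate case this is the ordinary ANOVA F ``(h^2/e^2) (df_e/df_h)``.
    """
    if dec.s == 0:
        raise DegenerateEffectError("effect matrix has rank 0; no F is defined")
    value = _f_from_eigenvalues(dec.eigenvalues, dec.df_h, dec.df_e, stattype)
    return ManovaF(stattype=stattype, value=value, df_h=dec.df_h, df_e=dec.df_e)


def eigen_contributions(dec: EffectDecomposition) -> np.ndarray:
    """Attribute each eigenvalue of H E^{-1} to the individual measures.

    Returns an ``(s, n)`` matrix ``k[i, j]`` of non-negative contribution
    coefficients satisfying the reconstruction identity

        sum_j k[i, j] * F_j = c_i * df_e / df_h     for every i,

    with ``F_j`` the per-measure univariate F values
    (:meth:`EffectDecomposition.univariate_f`).  Each eigenvalue is spread
    over measures proportionally to the squared loadings of its
    ``H E^{-1}`` eigenvector, then rescaled so the identity holds exactly.
    When H and E are both diagonal (genuinely uncorrelated measures) the
    eigenvectors are coordinate axes and the attribution reduces to a
    selection matrix, each eigenvalue claimed wholly by one measure.  For
    correlated measures the squared-loading rule keeps the recombined
    univariate F values statistically exchangeable with the multivariate
    F under the null, which is what calibrates the normalized statistics
    to their unit null expectation.
    """
    if dec.s == 0:
        raise DegenerateEffectError("no eigenvalues to attribute")
    n, s = dec.n, dec.s
    ratio = dec.df_e / dec.df_h
    F = dec.univariate_f()
    F = np.clip(F, 0.0, None)
    K = np.zeros((s, n))
    if np.all(F <= 0):
        logger.warning(
            "all per-measure F values are zero with a nonzero effect; "
            "falling back to uniform attribution"
        )
        K[:] = dec.eigenvalues[:, None] * ratio / n
        return K
    for i, c in enumerate(dec.eigenvalues):
        # eigenvector of H E^-1 itself: u = E v for the generalized pair
        u = dec.E @ dec.eigenvectors[:, i]
        norm = np.linalg.norm(u)
        if norm > 0:
            u = u / norm
        w = u**2
        w[F <= 0] = 0.0  # cannot carry mass on a zero-F measure
        tot = w.sum()
        w = w / tot if tot > 0 else (F > 0) / (F > 0).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            k_row = np.where(F > 0, c * ratio * w / F, 0.0)
        K[i] = k_row
    return K


def estimate_variance_components(
    dataset: FeatureDataset, measure: str
) -> VarianceComponents:
    """Method-of-moments variance components for one measure.

    On the subject x condition table with condition means removed:
    ``sigma_e2`` is the residual mean square and
    ``sigma_p2 = max(0, (MS_subject - MS_residual) / k)``.
    Negative subtractive estimates are clamped to zero.
    """
    k = dataset.n_conditions
    if k < 2:
        raise ValueError("variance components need >= 2 conditions to separate")
    j = dataset.measures.index(measure) if measure in dataset.measures else None
    if j is None:
        raise KeyError(f"unknown measure {measure!r}")
    Y = dataset.data[:, :, j]  # (S, k)
    S = Y.shape[0]
    Yc = Y - Y.mean(axis=0, keepdims=True)  # remove condition means
    subj = Yc.mean(axis=1)  # per-subject effect
    resid = Yc - subj[:, None]
    ss_resid = float((resid**2).sum())
    ms_resid = ss_resid / ((S - 1) * (k - 1))
    ms_subject = k * float((subj**2).sum()) / (S - 1)
    sigma_p2 = max(0.0, (ms_subject - ms_resid) / k)
    return VarianceComponents(sigma_e2=ms_resid, sigma_p2=sigma_p2)


def classical_mixed_f(dataset: FeatureDataset, measure: str) -> tuple[float, float]:
    """Classical mixed-model group test for one measure.

    Subjects are the random factor: the group effect is tested against the
    subject-within-group mean square, which enhances the error term with
    the person-effect variance.  Returns ``(F, tail probability)`` with
    degrees of freedom ``(G - 1, N_subjects - G)``.
    """
    if measure not in dataset.measures:
        raise KeyError(f"unknown measure {measure!r}")
    j = dataset.measures.index(measure)
    labels = dataset.group_labels
    G = len(labels)
    if G < 2:
        raise ValueError("need >= 2 groups")
    codes = dataset.group_codes()
    k = dataset.n_conditions
    subj_means = dataset.data[:, :, j].mean(axis=1)  # (S,)
    S = len(subj_means)
    if S - G < 1:
        raise ValueError("need at least 2 subjects per group for df_e >= 1")
    grand = subj_means.mean()
    ss_group = 0.0
    ss_within = 0.0
    for g in range(G):
        m = subj_means[codes == g]
        ss_group += len(m) * (m.mean() - grand) ** 2
        ss_within += ((m - m.mean()) ** 2).sum()
    ms_group = k * ss_group / (G - 1)
    ms_within = k * ss_within / (S - G)
    if ms_within == 0:
        warnings.warn("zero subject-within-group mean square; F is infinite")
        return float("inf"), 0.0
    f = ms_group / ms_within
    p = float(sps.f.sf(f, G - 1, S - G))
    return float(f), p
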