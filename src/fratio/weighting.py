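"""Bayesian hypothesis weighting and the weighted discriminant.

Each candidate feature combination corresponds to an alternative
hypothesis H1^i ("these measures differ between groups") tested at some
significance probability pi_i = P[B | H0].  With a flat prior
c = P[H0] and a common P[B | H1] = c2 across alternatives, Bayes'
theorem turns the test outcomes into posterior weights for the
hypotheses — and hence into fractional inclusion weights for the
measures spanning them.  For two nested alternatives the ratio of their
likelihood ratios against H0 reduces to pi_anchor / pi_other, the weight
with which the less significant solution's extra measures enter when the
more significant solution is anchored at weight 1.  For probabilities
that are not small a finite-pi correction multiplies in the odds factor
(1 - pi_other)/(1 - pi_anchor).

The resulting weighted feature vector feeds a two-class Fisher
discriminant.  Measures weighted exactly zero are dropped (reducing
dimensionality); note that because the Fisher axis incorporates the
inverse pooled covariance, nonzero diagonal rescaling of the inputs
changes the axis coordinates but not the induced classification — the
operative part of a fractional weight is thresholding to zero, while
the fractional values document the evidence each measure carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FeatureDataset, MeasureSubset, restrict

__all__ = [
    "HypothesisSpec",
    "WeightedFeatureVector",
    "DiscriminantResult",
    "posterior_probs",
    "likelihood_ratio",
    "relative_weight",
    "build_feature_weights",
    "weighted_discriminant",
]


@dataclass(frozen=True)
class HypothesisSpec:
    """One alternative hypothesis: a feature set tested at level pi.

    ``pi`` is the significance probability P[B | H0] attached to the set
    (e.g. 0.05 for a 95% solution), ``prior_c`` the a priori P[H0], and
    ``c2`` the common P[B | H1].
    """

    features: MeasureSubset
    pi: float
    prior_c: float = 0.5
    c2: float = 1.0

    def __post_init__(self) -> None:
        if isinstance(self.features, (list, tuple)):
            object.__setattr__(self, "features", MeasureSubset(tuple(self.features)))
        if not 0 < self.pi < 1:
            raise ValueError("pi must lie in (0, 1)")
        if not 0 < self.prior_c < 1:
            raise ValueError("prior_c must lie in (0, 1)")
        if not 0 < self.c2 <= 1:
            raise ValueError("c2 must lie in (0, 1]")


def posterior_probs(h: HypothesisSpec) -> tuple[float, float]:
    """Posterior probabilities (P[H0 | B], P[H1 | B]) given an outcome in B.

    ``P[H0 | B] = c pi / (c pi + c2 (1 - c))`` and its complement; the two
    sum to one.
    """
    c, pi, c2 = h.prior_c, h.pi, h.c2
    denom = c * pi + c2 * (1.0 - c)
    return c * pi / denom, c2 * (1.0 - c) / denom


def likelihood_ratio(h: HypothesisSpec) -> float:
    """Posterior odds of H1 against H0: c2 (1 - c) / (c pi).

    The weight with which the alternative is preferable when H0 carries
    weight 1; for the flat prior this is simply c2 / pi.
    """
    return h.c2 * (1.0 - h.prior_c) / (h.prior_c * h.pi)


def relative_weight(pi_anchor: float, pi_other: float, corrected: bool = True) -> float:
    """Weight of a less significant solution relative to the anchor.

    The ratio of the two solutions' likelihood ratios against H0 gives
    ``pi_anchor / pi_other`` (< 1: the anchor is the more significant
    hypothesis and carries weight 1).  That identification of P[B | H1]
    across alternatives is exact only for small pi; by default the
    posterior-odds-consistent finite-pi correction
    ``(1 - pi_other) / (1 - pi_anchor)`` is applied.
    """
    if not 0 < pi_anchor <= pi_other < 1:
        raise ValueError("need 0 < pi_anchor <= pi_other < 1 (anchor more significant)")
    w = pi_anchor / pi_other
    if corrected:
        w *= (1.0 - pi_other) / (1.0 - pi_anchor)
    return w


@dataclass(frozen=True)
class WeightedFeatureVector:
    """Measure -> inclusion weight in [0, 1]; weight-1 features are the anchor."""

    weights: dict
    anchor: tuple
    dropped: tuple = ()

    def __post_init__(self) -> None:
        ws = dict(self.weights)
        object.__setattr__(self, "weights", ws)
        if not ws:
            raise ValueError("empty weight map")
        vals = np.array(list(ws.values()), dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("weights must lie in [0, 1]")
        if not np.isclose(vals.max(), 1.0):
            raise ValueError("maximal weight must be 1 (the anchor)")
        for m in self.dropped:
            if ws.get(m, 0.0) != 0.0:
                raise ValueError(f"dropped measure {m!r} must have weight 0")

    def retained(self) -> list:
        return [m for m, w in self.weights.items() if w > 0]

    def to_dict(self) -> dict:
        return {
            "weights": dict(self.weights),
            "anchor": list(self.anchor),
            "dropped": list(self.dropped),
        }


def build_feature_weights(
    hypotheses: list[HypothesisSpec], drop_threshold: float = 0.05,
    corrected: bool = True,
) -> WeightedFeatureVector:
    """Turn a nested ladder of tested hypotheses into feature weights.

    ``hypotheses`` must be sorted by pi ascending, each later feature set
    extending an earlier one (nested alternatives).  The most significant
    set is anchored at weight 1; every feature first appearing in a later
    hypothesis enters with the relative weight of that hypothesis against
    the anchor.  Weights below ``drop_threshold`` are set to exactly 0 and
    the measure is dropped, reducing the feature-vector dimension.
    """
    if not hypotheses:
        raise ValueError("need at least one hypothesis")
    pis = [h.pi for h in hypotheses]
    if pis != sorted(pis):
        raise ValueError("hypotheses must be sorted by pi ascending")
    sets = [set(h.features) for h in hypotheses]
    for earlier, later in zip(sets, sets[1:]):
        if not earlier <= later:
            raise ValueError(
                "hypotheses must be nested: each later feature set must "
                "contain every earlier one"
            )
    anchor = hypotheses[0]
    weights: dict = {m: 1.0 for m in anchor.features}
    for h in hypotheses[1:]:
        w = relative_weight(anchor.pi, h.pi, corrected=corrected)
        for m in h.features:
            if m not in weights:
                weights[m] = w
    dropped = tuple(m for m, w in weights.items() if w < drop_threshold)
    for m in dropped:
        weights[m] = 0.0
    return WeightedFeatureVector(
        weights=weights, anchor=tuple(anchor.features), dropped=dropped
    )


@dataclass(frozen=True)
class DiscriminantResult:
    """Two-class discriminant outcome on the main axis."""

    axis_scores: np.ndarray
    predicted: tuple
    actual: tuple
    accuracy: float
    group_means: dict
    subjects: tuple = ()

    def to_dict(self) -> dict:
        return {
            "axis_scores": self.axis_scores.tolist(),
            "predicted": list(self.predicted),
            "actual": list(self.actual),
            "accuracy": self.accuracy,
            "group_means": {str(k): v for k, v in self.group_means.items()},
            "subjects": list(self.subjects),
        }


def _fisher_axis(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher direction w = Sw^-1 (mu0 - mu1) for two classes."""
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    X0 = X[y == 0] - mu0
    X1 = X[y == 1] - mu1
    Sw = X0.T @ X0 + X1.T @ X1
    try:
        return np.linalg.solve(Sw, mu0 - mu1)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; use fewer measures"
        ) from exc


def weighted_discriminant(
    dataset: FeatureDataset,
    weights: WeightedFeatureVector,
    condition,
    leave_one_out: bool = False,
) -> DiscriminantResult:
    """Classify subjects by a Fisher discriminant on weighted measures.

    Measures with weight zero are excluded.  Each retained measure is
    standardized (zero mean, unit s.d. across subjects at the requested
    condition) and multiplied by its weight; the two-class Fisher axis is
    computed, subjects are projected onto it and classified by the nearer
    group mean.  Resubstitution accuracy is reported by default;
    ``leave_one_out`` refits the axis without each held-out subject.
    """
    labels = dataset.group_labels
    if len(labels) != 2:
        raise ValueError("the discriminant is defined for exactly 2 groups")
    if condition not in dataset.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    retained = [m for m in dataset.measures if weights.weights.get(m, 0.0) > 0]
    if not retained:
        raise ValueError("no measures with positive weight present in the dataset")
    sub = restrict(dataset, measures=retained, conditions=[condition])
    X = sub.data[:, 0, :]  # (S, n_retained)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [m for m, s in zip(retained, sd) if s == 0]
        raise ValueError(f"zero variance in measures {bad}; cannot standardize")
    w_vec = np.array([weights.weights[m] for m in retained])
    Z = (X - X.mean(axis=0)) / sd * w_vec
    y = sub.group_codes()

    if leave_one_out:
        scores = np.empty(len(y))
        preds = np.empty(len(y), dtype=int)
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            axis = _fisher_axis(Z[mask], y[mask])
            s = Z[i] @ axis
            m0 = Z[mask][y[mask] == 0] @ axis
            m1 = Z[mask][y[mask] == 1] @ axis
            scores[i] = s
            preds[i] = 0 if abs(s - m0.mean()) <= abs(s - m1.mean()) else 1
        axis = _fisher_axis(Z, y)
    else:
        axis = _fisher_axis(Z, y)
        scores = Z @ axis
        m0 = scores[y == 0].mean()
        m1 = scores[y == 1].mean()
        preds = np.where(np.abs(scores - m0) <= np.abs(scores - m1), 0, 1)

    accuracy = float(np.mean(preds == y))
    full_scores = Z @ axis
    gmeans = {labels[g]: float(full_scores[y == g].mean()) for g in (0, 1)}
    return DiscriminantResult(
        axis_scores=scores,
        predicted=tuple(labels[i] for i in preds),
        actual=tuple(labels[i] for i in y),
        accuracy=accuracy,
        group_means=gmeans,
        subjects=sub.subjects,
    )
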