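"""Synthetic feature-table generator for the null and power studies.

The generative model mirrors the repeated-measures design the tests are
built for: each simulated subject carries one random person effect per
measure, shared across all conditions, on top of fixed condition offsets,
an optional fixed group offset, and i.i.d. measurement error:

    value(s in group g, condition t, measure j)
        = condition_offset[t] + group_effect[g] + P[s, j] + eps[s, t, j]

with P ~ N(0, sigma_p^2) drawn once per subject and measure and
eps ~ N(0, sigma_e^2) per cell.  Under the null hypothesis all group
effects are equal (conventionally zero), so any between-group difference
is driven purely by the sampled person effects and noise.

Defaults reproduce the canonical study design: 2 groups of 15 subjects,
4 conditions, condition offsets {0, 1, 2, 3} (their magnitude is
irrelevant to the group test — they are fixed and cancel in the
between-group contrasts; they are kept to mimic realistic state
structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .data import FeatureDataset

__all__ = ["SimulationParams", "simulate_dataset"]


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for a synthetic feature dataset.

    ``group_effects`` are fixed per-group offsets Delta_a (all zero under
    the null).  ``between_measure_corr`` equicorrelates the measurement
    errors across measures; person effects stay independent between
    measures.  ``sampler``, if given, replaces the standard-normal deviate
    source with any zero-mean unit-variance generator (signature
    ``sampler(rng, shape) -> ndarray``) — the Monte Carlo calibration
    carries over to non-normal noise unchanged.
    """

    k: int = 4
    n_groups: int = 2
    subjects_per_group: int = 15
    sigma_e: float = 1.0
    sigma_p: float = 1.0
    condition_offsets: tuple = (0.0, 1.0, 2.0, 3.0)
    group_effects: tuple = (0.0, 0.0)
    n_measures: int = 1
    between_measure_corr: float = 0.0
    seed: int | None = None
    sampler: Callable | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "condition_offsets", tuple(float(x) for x in self.condition_offsets)
        )
        object.__setattr__(
            self, "group_effects", tuple(float(x) for x in self.group_effects)
        )
        if self.sigma_e < 0 or self.sigma_p < 0:
            raise ValueError("standard deviations must be >= 0")
        if len(self.condition_offsets) != self.k:
            raise ValueError(
                f"need {self.k} condition offsets, got {len(self.condition_offsets)}"
            )
        if len(self.group_effects) != self.n_groups:
            raise ValueError(
                f"need {self.n_groups} group effects, got {len(self.group_effects)}"
            )
        if not -1.0 < self.between_measure_corr < 1.0:
            raise ValueError("between_measure_corr must lie in (-1, 1)")
        if self.subjects_per_group < 2:
            raise ValueError("need >= 2 subjects per group")
        if self.n_measures < 1 or self.k < 1 or self.n_groups < 1:
            raise ValueError("k, n_groups, n_measures must be >= 1")

    def under_null(self) -> "SimulationParams":
        """The same design with all fixed group effects removed."""
        return replace(self, group_effects=(0.0,) * self.n_groups)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_groups": self.n_groups,
            "subjects_per_group": self.subjects_per_group,
            "sigma_e": self.sigma_e,
            "sigma_p": self.sigma_p,
            "condition_offsets": list(self.condition_offsets),
            "group_effects": list(self.group_effects),
            "n_measures": self.n_measures,
            "between_measure_corr": self.between_measure_corr,
            "seed": self.seed,
        }


def _draw(params: SimulationParams, rng: np.random.Generator, shape) -> np.ndarray:
    if params.sampler is not None:
        out = np.asarray(params.sampler(rng, shape), dtype=float)
        if out.shape != tuple(shape):
            raise ValueError("sampler returned wrong shape")
        return out
    return rng.standard_normal(shape)


def simulate_dataset(
    params: SimulationParams,
    seed: int | np.random.SeedSequence | None = None,
) -> FeatureDataset:
    """Draw one synthetic dataset from the generative model.

    Subjects are labeled into groups in contiguous blocks (the first block
    is group "g1", the next "g2", ...).  Fully reproducible from ``seed``
    (which overrides ``params.seed`` when given).
    """
    if seed is None:
        seed = params.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    G, spg, k, n = params.n_groups, params.subjects_per_group, params.k, params.n_measures
    S = G * spg
    person = params.sigma_p * _draw(params, rng, (S, n))  # one draw per subject/measure
    eps = params.sigma_e * _draw(params, rng, (S, k, n))
    rho = params.between_measure_corr
    if rho != 0.0 and n > 1:
        corr = np.full((n, n), rho)
        np.fill_diagonal(corr, 1.0)
        L = np.linalg.cholesky(corr)
        eps = eps @ L.T

    offsets = np.asarray(params.condition_offsets)[None, :, None]
    geff = np.repeat(np.asarray(params.group_effects), spg)[:, None, None]
    data = offsets + geff + person[:, None, :] + eps

    subjects = tuple(f"s{i + 1:03d}" for i in range(S))
    groups = tuple(f"g{g + 1}" for g in range(G) for _ in range(spg))
    conditions = tuple(f"c{t + 1}" for t in range(k))
    measures = tuple(f"x{j + 1}" for j in range(n))
    return FeatureDataset(
        subjects=subjects, groups=groups, conditions=conditions,
        measures=measures, data=data,
    )
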