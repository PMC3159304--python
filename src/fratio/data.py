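"""Feature-table containers and delimited-text I/O.

The central container is :class:`FeatureDataset`: a complete, balanced
subjects x conditions x measures table with a group label per subject.
This is the long-format layout produced by upstream signal analysis
(one row per subject and condition, one column per extracted measure
such as a spectral band power or a fractal dimension estimate).

Incomplete or unbalanced designs are rejected at construction; the
variance decompositions downstream assume every cell is filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureDataset",
    "MeasureSubset",
    "TableDialect",
    "read_feature_table",
    "write_feature_table",
    "restrict",
]


class FeatureTableError(ValueError):
    """Raised when a feature table violates the completeness contract."""


@dataclass(frozen=True)
class TableDialect:
    """Column naming for delimited feature tables.

    Every column not named here is treated as a numeric measure column.
    """

    subject: str = "subject"
    group: str = "group"
    condition: str = "condition"


@dataclass(frozen=True)
class MeasureSubset:
    """An ordered, duplicate-free subset of a dataset's measure names."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise ValueError("measure subset must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate measure names in subset: {names}")

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class FeatureDataset:
    """Complete balanced subjects x conditions x measures table.

    Parameters
    ----------
    subjects
        Subject identifiers, one per row block.
    groups
        Group label per subject, aligned with ``subjects``.  At least two
        subjects per group are required.
    conditions
        Condition (state/treatment) labels, ``k`` of them.
    measures
        Measure names, ``n`` of them.
    data
        Array of shape ``(n_subjects, k, n)`` holding every cell value.
    """

    subjects: tuple
    groups: tuple
    conditions: tuple
    measures: tuple
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "measures", tuple(str(m) for m in self.measures))
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        self._validate()

    def _validate(self) -> None:
        S, k, n = len(self.subjects), len(self.conditions), len(self.measures)
        if len(set(self.subjects)) != S:
            raise FeatureTableError("duplicate subject ids")
        if len(self.groups) != S:
            raise FeatureTableError("one group label per subject required")
        if n < 1 or k < 1:
            raise FeatureTableError("need at least one measure and one condition")
        if len(set(self.conditions)) != k:
            raise FeatureTableError("duplicate condition labels")
        if len(set(self.measures)) != n:
            raise FeatureTableError("duplicate measure names")
        if self.data.shape != (S, k, n):
            raise FeatureTableError(
                f"data shape {self.data.shape} does not match "
                f"(subjects={S}, conditions={k}, measures={n})"
            )
        if not np.all(np.isfinite(self.data)):
            raise FeatureTableError("non-finite value in feature table")
        counts = pd.Series(self.groups).value_counts()
        if len(counts) < 1:
            raise FeatureTableError("no groups")
        small = counts[counts < 2]
        if not small.empty:
            raise FeatureTableError(
                f"each group needs >= 2 subjects; too small: {dict(small)}"
            )

    # -- basic descriptors -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_measures(self) -> int:
        return len(self.measures)

    @property
    def group_of(self) -> dict:
        """Map subject id -> group label."""
        return dict(zip(self.subjects, self.groups))

    @property
    def group_labels(self) -> tuple:
        """Distinct group labels in order of first appearance."""
        seen: dict = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return tuple(seen)

    def group_codes(self) -> np.ndarray:
        """Integer group index per subject (order of first appearance)."""
        labels = {g: i for i, g in enumerate(self.group_labels)}
        return np.array([labels[g] for g in self.groups], dtype=np.intp)

    def value(self, subject, condition, measure) -> float:
        s = self.subjects.index(subject)
        c = self.conditions.index(condition)
        m = self.measures.index(measure)
        return float(self.data[s, c, m])

    # -- DataFrame round trip ----------------------------------------------

    def to_frame(self, dialect: TableDialect | None = None) -> pd.DataFrame:
        dialect = dialect or TableDialect()
        S, k = self.n_subjects, self.n_conditions
        meas = sorted(self.measures)
        order = [self.measures.index(m) for m in meas]
        rows = {
            dialect.subject: np.repeat(self.subjects, k),
            dialect.group: np.repeat(self.groups, k),
            dialect.condition: np.tile(self.conditions, S),
        }
        flat = self.data.reshape(S * k, self.n_measures)
        for m, j in zip(meas, order):
            rows[m] = flat[:, j]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, dialect: TableDialect | None = None
    ) -> "FeatureDataset":
        dialect = dialect or TableDialect()
        for col in (dialect.subject, dialect.group, dialect.condition):
            if col not in frame.columns:
                raise FeatureTableError(f"missing required column {col!r}")
        id_cols = {dialect.subject, dialect.group, dialect.condition}
        measures = [c for c in frame.columns if c not in id_cols]
        if not measures:
            raise FeatureTableError("no measure columns found")
        for m in measures:
            vals = pd.to_numeric(frame[m], errors="coerce")
            bad = vals.isna() & frame[m].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise FeatureTableError(
                    f"non-numeric value in measure column {m!r} at row {row}"
                )
            if vals.isna().any():
                row = int(np.flatnonzero(vals.isna().to_numpy())[0])
                raise FeatureTableError(f"missing value in column {m!r} at row {row}")

        subjects = list(dict.fromkeys(frame[dialect.subject]))
        conditions = list(dict.fromkeys(frame[dialect.condition]))
        gmap: dict = {}
        for s, g in zip(frame[dialect.subject], frame[dialect.group]):
            if s in gmap and gmap[s] != g:
                raise FeatureTableError(f"subject {s!r} has conflicting group labels")
            gmap[s] = g

        pivot = frame.set_index([dialect.subject, dialect.condition])
        expected = {(s, c) for s in subjects for c in conditions}
        got = set(pivot.index)
        missing = expected - got
        if missing:
            some = sorted(missing, key=str)[:5]
            raise FeatureTableError(
                f"incomplete design: {len(missing)} missing (subject, condition) "
                f"cells, e.g. {some}"
            )
        if len(got) != len(frame):
            raise FeatureTableError("duplicate (subject, condition) rows")

        S, k, n = len(subjects), len(conditions), len(measures)
        data = np.empty((S, k, n), dtype=float)
        block = pivot[measures].astype(float)
        for i, s in enumerate(subjects):
            for j, c in enumerate(conditions):
                data[i, j, :] = block.loc[(s, c)].to_numpy()
        return cls(
            subjects=tuple(subjects),
            groups=tuple(gmap[s] for s in subjects),
            conditions=tuple(conditions),
            measures=tuple(measures),
            data=data,
        )


def read_feature_table(
    path: str | Path, dialect: TableDialect | None = None
) -> FeatureDataset:
    """Read a comma-delimited long-format feature table.

    The file must have a header naming the subject, group and condition
    columns (see :class:`TableDialect`) plus at least one numeric measure
    column.  The design must be complete: every subject must appear under
    every condition exactly once.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str)
    return FeatureDataset.from_frame(frame, dialect)


def write_feature_table(
    dataset: FeatureDataset, path: str | Path, dialect: TableDialect | None = None
) -> None:
    """Write a dataset as a comma-delimited long-format table.

    Measure columns are emitted in sorted name order so output is
    deterministic regardless of construction order.
    """
    dataset.to_frame(dialect).to_csv(path, index=False)


def restrict(
    dataset: FeatureDataset,
    measures: MeasureSubset | Sequence[str] | None = None,
    conditions: Iterable | None = None,
) -> FeatureDataset:
    """Return the dataset restricted to a subset of measures and/or conditions.

    The result is still complete and balanced; subjects and groups are
    unchanged.  Selections on the two axes commute.
    """
    if measures is None:
        meas_names = dataset.measures
    else:
        meas_names = tuple(measures.names if isinstance(measures, MeasureSubset) else measures)
    for m in meas_names:
        if m not in dataset.measures:
            raise KeyError(f"unknown measure {m!r}")
    if conditions is None:
        cond_names = dataset.conditions
    else:
        cond_names = tuple(conditions)
    for c in cond_names:
        if c not in dataset.conditions:
            raise KeyError(f"unknown condition {c!r}")
    mi = [dataset.measures.index(m) for m in meas_names]
    ci = [dataset.conditions.index(c) for c in cond_names]
    return FeatureDataset(
        subjects=dataset.subjects,
        groups=dataset.groups,
        conditions=cond_names,
        measures=meas_names,
        data=dataset.data[:, ci][:, :, mi],
    )
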