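import numpy as np
import pytest

from fratio import FeatureDataset, SimulationParams, simulate_dataset


@pytest.fixture
def tiny_dataset() -> FeatureDataset:
    """Two groups of three subjects, one condition, one measure: {1,2,3} vs {4,5,6}."""
    return FeatureDataset(
        subjects=("a", "b", "c", "d", "e", "f"),
        groups=("g1",) * 3 + ("g2",) * 3,
        conditions=("c1",),
        measures=("x",),
        data=np.array([1.0, 2, 3, 4, 5, 6]).reshape(6, 1, 1),
    )


@pytest.fixture
def null_params() -> SimulationParams:
    """Canonical null design: 2 x 15 subjects, 4 conditions, unit variances."""
    return SimulationParams()


@pytest.fixture
def small_dataset() -> FeatureDataset:
    """A reproducible 2 x 6-subject, 3-condition, 2-measure null dataset."""
    params = SimulationParams(
        k=3, subjects_per_group=6, condition_offsets=(0.0, 1.0, 2.0), n_measures=2
    )
    return simulate_dataset(params, seed=11)


def random_dataset(seed: int, n_measures: int = 2, subjects_per_group: int = 5,
                   k: int = 2) -> FeatureDataset:
    """Small random dataset for oracle comparisons."""
    params = SimulationParams(
        k=k,
        subjects_per_group=subjects_per_group,
        condition_offsets=tuple(float(i) for i in range(k)),
        n_measures=n_measures,
    )
    return simulate_dataset(params, seed=seed)
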