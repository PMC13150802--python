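import numpy as np
import pytest

from sensorselect import (
    ClassGaussian,
    ClassLabeling,
    PipelineConfig,
    ResponseTable,
)


@pytest.fixture
def two_class_table():
    """6 samples x 2 sensors, two well-separated classes of 3 replicates."""
    values = np.array(
        [
            [0.0, 0.1],
            [0.2, -0.1],
            [-0.1, 0.0],
            [5.0, 5.1],
            [5.2, 4.9],
            [4.9, 5.0],
        ]
    )
    table = ResponseTable(values, ("S1", "S2"), tuple(f"r{i}" for i in range(6)))
    labeling = ClassLabeling(np.array([0, 0, 0, 1, 1, 1]), ("A", "B"))
    return table, labeling


@pytest.fixture
def fast_config():
    return PipelineConfig(mc_samples=1000, grid_resolution=80, seed=0)


def make_gaussian(class_index, mean, cov, n_k=5):
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    return ClassGaussian(class_index, mean, cov, np.linalg.eigvalsh(cov)[::-1], n_k)


@pytest.fixture
def gaussian_factory():
    return make_gaussian
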