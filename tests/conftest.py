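import numpy as np
import pytest

from taskconnectome.core import Partition, RoiTimeSeries
from taskconnectome.gppi import DifferenceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_partition():
    # modules A = {0,1,2}, B = {3,4}
    return Partition(labels=[0, 0, 0, 1, 1])


@pytest.fixture
def small_difference():
    # positive edges 0->1, 1->2, 0->3; negative edge 4->0
    v = np.zeros((5, 5), dtype=int)
    v[0, 1] = v[1, 2] = v[0, 3] = 1
    v[4, 0] = -1
    return DifferenceMatrix(values=v)


def random_difference_matrix(rng, n, p_edge=0.15):
    """Random ternary directed matrix for oracle comparisons."""
    v = rng.choice([0, 1, -1], size=(n, n),
                   p=[1 - p_edge, p_edge / 2, p_edge / 2])
    np.fill_diagonal(v, 0)
    return DifferenceMatrix(values=v)


@pytest.fixture
def series_factory():
    def make(values, tr=0.72, runs=None):
        return RoiTimeSeries(values=np.asarray(values, dtype=float), tr=tr,
                             run_labels=runs)
    return make
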