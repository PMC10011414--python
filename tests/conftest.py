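import numpy as np
import pytest

from sdmgap.grid import GridSpec
from sdmgap.landscape import PAMask, PartitionRasters, simulate_climate


@pytest.fixture(scope="session")
def grid50():
    return GridSpec(50, 50)


@pytest.fixture(scope="session")
def climate50(grid50):
    return simulate_climate(grid50, seed=42)


@pytest.fixture
def checker_pa(grid50):
    """PA mask with a strict (II) block top-left and a non-strict (V) block top-right."""
    classes = np.zeros(grid50.shape, dtype=np.int8)
    classes[:10, :10] = 3  # II -> strict
    classes[:10, 40:] = 6  # V -> all only
    return PAMask(grid50, classes)


@pytest.fixture
def one_region_partition(grid50):
    z = np.zeros(grid50.shape, dtype=np.int32)
    return PartitionRasters(grid50, z, z.copy())
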