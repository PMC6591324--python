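import pytest

from gstfam import io_formats
from gstfam.synthetic_data import DatasetParams, simulate_dataset


@pytest.fixture(scope="session")
def table1():
    return io_formats.read_packaged_catalog()


@pytest.fixture(scope="session")
def dataset():
    """One seeded synthetic dataset shared across the suite."""
    return simulate_dataset(DatasetParams(), seed=3)
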