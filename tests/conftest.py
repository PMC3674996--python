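import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from orimark import BinGrid, GenomeLayout

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def layout_small() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (100_000, 50_000))


@pytest.fixture
def grid_small(layout_small) -> BinGrid:
    return BinGrid(layout_small, 100)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(910729)
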