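import warnings

import numpy as np
import pytest

from stdual import generate_synthetic_st
from stdual.model import PipelineConfig, SpatialDomainModel

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def grid_fixture():
    """Default synthetic grid: 20x20 spots, 4 domains, 300 genes."""
    return generate_synthetic_st(seed=7)


@pytest.fixture(scope="session")
def small_fixture():
    """Small grid for cheap tests."""
    return generate_synthetic_st(
        n_side=10, n_domains=2, n_genes=120, n_markers_per_domain=6,
        n_program_genes=20, seed=11,
    )


@pytest.fixture(scope="session")
def fitted_result(grid_fixture):
    """One full pipeline fit shared across tests (seed 7)."""
    ds, truth = grid_fixture
    model = SpatialDomainModel(ds, n_domains=4, config=PipelineConfig.fixture())
    return model.fit(seed=7), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
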