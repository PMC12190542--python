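import numpy as np
import pytest

from radfrac import SimConfig, SimGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def rich_config():
    """A small, nutrient-saturated world: nothing starves or arrests."""
    return SimConfig(
        grid_size=11, n_healthy_init=0, n_cancer_init=1, n_sources=5,
        glucose_init=1.0, oxygen_init=1.0,
        source_glucose_rate=1e-3, source_oxygen_rate=1e-3,
        density_cap=None, healthy_density_cap=None,
    )


def bare_grid(size: int = 11, glucose: float = 1.0, oxygen: float = 1.0,
              seed: int = 0) -> SimGrid:
    """An empty grid with uniform nutrient stores, for hand-built scenarios."""
    g = SimGrid(
        size,
        sources=np.array([0], dtype=np.int64),
        glucose=np.full((size, size), glucose),
        oxygen=np.full((size, size), oxygen),
        rng=np.random.default_rng(seed),
    )
    return g
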