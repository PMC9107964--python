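import numpy as np
import pytest

from retmosaic import MosaicField, SimConfig, Window, simulate_field


@pytest.fixture(scope="session")
def central_config():
    """Matched parameters of a dense central field (292 cells, 9.01±0.39 μm)."""
    return SimConfig(n_cells=292, diameter_mean=9.01, diameter_sd=0.39)


@pytest.fixture(scope="session")
def hardcore_field(central_config):
    return simulate_field(central_config, trial_seed=42)


@pytest.fixture()
def uniform_field():
    """Factory: n uniform random points in a window (no size constraint)."""

    def make(n, seed=0, window=None):
        window = window or Window()
        rng = np.random.default_rng(seed)
        return MosaicField(
            x=rng.uniform(window.x_min, window.x_max, n),
            y=rng.uniform(window.y_min, window.y_max, n),
            window=window,
        )

    return make
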