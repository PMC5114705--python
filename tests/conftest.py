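import numpy as np
import pytest

import nicheshift as ns
from nicheshift.raster_stack import GridSpec, Layer, RasterStack


@pytest.fixture
def grid4() -> GridSpec:
    """4 × 4 one-degree grid centered on the equator."""
    return GridSpec(
        lon_min=-2.0, lon_max=2.0, lat_min=-2.0, lat_max=2.0,
        cell_size=1.0, n_rows=4, n_cols=4,
    )


@pytest.fixture
def tiny_stack(grid4) -> RasterStack:
    """Two aligned layers with one shared masked cell at (0, 0)."""
    rng = np.random.default_rng(11)
    mask = np.zeros((4, 4), dtype=bool)
    mask[0, 0] = True
    a = Layer("BIO1", rng.normal(20.0, 3.0, (4, 4)), mask.copy())
    b = Layer("BIO12", rng.normal(100.0, 20.0, (4, 4)), np.zeros((4, 4), bool))
    return RasterStack(grid4, [a, b])


@pytest.fixture(scope="session")
def recovery_bundle():
    """One seeded synthetic experiment shared by the slower integration tests."""
    cfg = ns.recovery_config()
    return ns.make_truth(cfg, seed=42, scenarios=[(2070, 8.5)])
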