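import numpy as np
import pytest

from grasscast.rasters import EnvStack, GridGeometry
from grasscast.synthetic import LandscapeConfig, generate_env_stack


@pytest.fixture
def geom10():
    return GridGeometry(10, 10, 0.0, 0.0, 1.0)


@pytest.fixture(scope="session")
def demo_stack():
    """32x32 autocorrelated stack: 3 climate + 2 static layers."""
    return generate_env_stack(LandscapeConfig(n_rows=32, n_cols=32, seed=7))


@pytest.fixture
def tiny_stack():
    """4x4 two-layer stack with one nodata cell."""
    rng = np.random.default_rng(3)
    a = rng.standard_normal((4, 4))
    b = rng.standard_normal((4, 4))
    a[0, 0] = np.nan
    geom = GridGeometry(4, 4, 0.0, 0.0, 1.0)
    return EnvStack({"x1": a, "x2": b}, geom, {"x1": "climate", "x2": "static"})
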