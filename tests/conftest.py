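import numpy as np
import pytest

from cropfuse import GridSpec, WorldConfig, gen_world
from cropfuse.pipeline import run_pipeline


@pytest.fixture(scope="session")
def world():
    """Default synthetic world (seed 0) shared across tests."""
    return gen_world(WorldConfig(seed=0))


@pytest.fixture(scope="session")
def pipeline_result(world):
    """Full pipeline run on the default world, adjustment included."""
    return run_pipeline(world, adjust=True)


@pytest.fixture()
def toy_spec():
    """A coarse 10x20 grid covering the whole globe (18 degrees per cell)."""
    return GridSpec(resolution=18.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
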