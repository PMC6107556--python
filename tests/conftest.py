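import numpy as np
import pytest

from somitekit.io import VoxelGeometry
from somitekit.report import run_three_stage_scenario


@pytest.fixture(scope="session")
def geometry() -> VoxelGeometry:
    return VoxelGeometry()


@pytest.fixture(scope="session")
def three_stage_scenario() -> dict:
    """One full early/mid/late pipeline run, shared across tests."""
    return run_three_stage_scenario(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
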