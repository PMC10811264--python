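import numpy as np
import pytest

from omnineck.controller import ControllerConfig, ControllerGains
from omnineck.io_cli import StpFixtureSpec, generate_stp_fixture
from omnineck.plant import HeadNeckPlant
from omnineck.stp import (
    StpSet,
    combine_sources,
    default_registry,
    normalize_per_direction,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def source_records():
    return generate_stp_fixture(StpFixtureSpec(seed=1))


@pytest.fixture(scope="session")
def stps(source_records, registry) -> StpSet:
    right = combine_sources(source_records, registry)
    return normalize_per_direction(StpSet.from_right_patterns(right))


@pytest.fixture(scope="session")
def plant() -> HeadNeckPlant:
    return HeadNeckPlant()


@pytest.fixture
def default_gains() -> ControllerGains:
    return ControllerGains(0.8, 1e-5, 250.0)


@pytest.fixture
def translational_config() -> ControllerConfig:
    return ControllerConfig(mode="translational", baseline_scale=0.05)


@pytest.fixture
def rotational_config() -> ControllerConfig:
    return ControllerConfig(mode="rotational", baseline_scale=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
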