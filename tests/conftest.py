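import numpy as np
import pytest
from hypothesis import settings

from plsbeam.forward import compute_leadfield
from plsbeam.geometry import (HeadSphere, build_helmet_array, build_source_grid,
                              partition_regions)
from plsbeam.harness import ExperimentConfig, ExperimentContext, build_context

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def sphere():
    return HeadSphere()


@pytest.fixture(scope="session")
def helmet(sphere):
    return build_helmet_array(102, sphere)


@pytest.fixture(scope="session")
def partition(helmet, sphere):
    return partition_regions(helmet, sphere)


@pytest.fixture(scope="session")
def default_context() -> ExperimentContext:
    """Standard experiment geometry: 102-site helmet, ~1,100-point grid,
    planar-gradiometer lead field."""
    return build_context(ExperimentConfig())


@pytest.fixture(scope="session")
def small_context() -> ExperimentContext:
    """Coarse, fast geometry for pipeline-level tests (24 sites, ~150 points)."""
    cfg = ExperimentConfig(n_sites=24, grid_spacing=20.0)
    return build_context(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
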