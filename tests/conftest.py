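import numpy as np
import pytest

from pfdisturb import (
    AssessmentConfig,
    BootstrapSpec,
    DisturbanceLayers,
    Grid,
    assess,
    fixture_config,
    generate,
)


@pytest.fixture(scope="session")
def fixture_land():
    """The tiny deterministic 64x64 landscape bundle."""
    return generate(fixture_config(seed=7))


@pytest.fixture(scope="session")
def fixture_assessment(fixture_land):
    cfg = AssessmentConfig(bootstrap=BootstrapSpec(n_iter=500, seed=7), shifts=(-1, 0, 1))
    return assess(fixture_land.layers, fixture_land.polygons, fixture_land.datasets, cfg)


def make_layers(year, forest=None, severity=None, cell_size=30.0, **kw):
    """Small hand-built DisturbanceLayers from a year array."""
    year = np.asarray(year, dtype=np.int16)
    grid = Grid(*year.shape, cell_size=cell_size, origin=(0.0, year.shape[0] * cell_size))
    if forest is None:
        forest = np.ones(year.shape, dtype=bool)
    if severity is None:
        severity = np.where(year > 0, 0.5, -1.0).astype(np.float32)
    return DisturbanceLayers(grid=grid, year=year, severity=severity, forest=forest, **kw)


@pytest.fixture
def layers_factory():
    return make_layers
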