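import numpy as np
import pytest

from solvmap import (
    Detector,
    ImageGrid,
    ProjectionOperator,
    ViewSet,
    generate_phantom,
    make_geometry,
)


@pytest.fixture(scope="session")
def grid16():
    return ImageGrid(16, 16, 1.0)


@pytest.fixture(scope="session")
def toy16(grid16):
    """Untruncated, full-column-rank 16x16 system: 23 bins cover the grid
    diagonal (22.6), 36 views over 180 degrees."""
    geom = make_geometry(grid16, Detector(23, 1.0, 0.0), ViewSet(36, 0.0, 5.0))
    return geom, ProjectionOperator(geom)


@pytest.fixture(scope="session")
def toy16_truth(grid16):
    """Smooth strictly positive 16x16 target (ML-EM converges to interior
    positive solutions much faster than to ones with zeros)."""
    ph = generate_phantom(3, grid16)
    return ph.image * 0.8 + 0.2


@pytest.fixture(scope="session")
def toy24_truncated():
    """Under-determined truncated 24x24 system (396 rays < 576 unknowns):
    11-bin detector offset +3, 36 views."""
    geom = make_geometry(ImageGrid(24, 24, 1.0), Detector(11, 1.0, 3.0),
                         ViewSet(36, 0.0, 5.0))
    return geom, ProjectionOperator(geom)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
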