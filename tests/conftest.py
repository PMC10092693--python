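import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mitoquant.io import VoxelSpacing
from mitoquant.phantom import PhantomSpec, generate_network, rasterize


@pytest.fixture(scope="session")
def default_truth():
    """A default filamentous single-cell phantom ground truth."""
    return generate_network(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def small_spec():
    """A reduced-size phantom spec for full-pipeline tests (keeps raster
    volumes small while preserving tube radius >= 2 in-plane voxels)."""
    return PhantomSpec(
        shape=(14, 96, 96),
        spacing=VoxelSpacing(0.15, 0.15, 0.6),
        n_tubules=6,
        tubule_length_um=(2.0, 5.0),
        tubule_radius_um=0.4,
        cell_radius_um=3.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return generate_network(small_spec)


@pytest.fixture(scope="session")
def small_raster(small_truth):
    mito, _ = rasterize(small_truth, noise=False)
    return mito
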