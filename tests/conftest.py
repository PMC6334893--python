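import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gradmap import (
    PlantedModel,
    make_atlas,
    make_cluster,
    make_reference_space,
)


@pytest.fixture(scope="session")
def ref():
    """Miniature reference space (~1350 gray-matter voxels)."""
    return make_reference_space(shape=(16, 18, 16), mask_fraction=0.3)


@pytest.fixture(scope="session")
def model(ref):
    return PlantedModel(n_voxels=ref.n_mask_voxels, seed=11)


@pytest.fixture(scope="session")
def atlas(ref, model):
    return make_atlas(ref, model)


@pytest.fixture(scope="session")
def cluster17(ref):
    """A 17-voxel binary in-mask cluster on the reference grid."""
    return make_cluster(ref, n_voxels=17, seed=3)
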