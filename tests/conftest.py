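import numpy as np
import pytest

from neurodc.dc import MaskedBOLD
from neurodc.grids import ToyGeometry, generate_toy_atlas, generate_toy_geometry


@pytest.fixture(scope="session")
def small_geometry():
    """8^3 spherical mask, ~140 voxels: enough structure, fast DC."""
    return generate_toy_geometry(shape=(8, 8, 8), mask_rule="sphere", radius=3.2)


@pytest.fixture(scope="session")
def small_atlas(small_geometry):
    return generate_toy_atlas(small_geometry, n_regions=5, seed=11)


@pytest.fixture()
def micro_bold():
    """The 4-voxel worked example; series repeated to reach 8 timepoints
    (Pearson correlations are unchanged by repetition)."""
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[0, 0, :] = True
    geom = ToyGeometry(shape=(4, 4, 4), voxel_size_mm=(3.0, 3.0, 3.0), mask=mask)
    coords = geom.mask_coordinates()
    series = np.array(
        [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1], [1, 3, 2, 4]], dtype=float
    )
    data = np.tile(series, 2)
    return MaskedBOLD(data=data, geometry=geom, voxel_index=coords)
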