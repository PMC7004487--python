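import numpy as np
import pytest

from gustaquant import preprocess, synthetic
from gustaquant.datatypes import ImageStack


SMALL_BUD_PARAMS = dict(
    stack_shape=(16, 96, 96),
    n_buds=1,
    bud_semiaxes_um=(6.0, 8.0, 8.0),
)


@pytest.fixture(scope="session")
def small_bud():
    """One default-noise bud stack shared by the recovery tests."""
    params = synthetic.BudSimParams(seed=2, **SMALL_BUD_PARAMS)
    return synthetic.generate_bud_stack(params)


@pytest.fixture(scope="session")
def small_bud_masks(small_bud):
    stack, _truth = small_bud
    return {
        ch: preprocess.binarize_channel(stack, ch) for ch in ("GFP", "P2X3")
    }


@pytest.fixture(scope="session")
def ganglion_values():
    """Drawn normalized intensities with true classes, n = 500."""
    params = synthetic.GanglionSimParams(n_cells=500, seed=11)
    return synthetic.draw_cell_intensities(params)


def make_stack(voxels, channel_names=("ch",), voxel_size=(1.0, 1.0, 1.0), bit_depth=8):
    """Small helper: wrap raw (C,Z,Y,X) or (Z,Y,X) data as an ImageStack."""
    voxels = np.asarray(voxels)
    if voxels.ndim == 3:
        voxels = voxels[None]
    return ImageStack(voxels, voxel_size, channel_names, bit_depth)
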