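import numpy as np
import pytest

import clrt


@pytest.fixture(scope="session")
def water_box_2mm():
    """Coarse homogeneous water phantom with a 4.4 mm PTV (fast fixture)."""
    return clrt.make_phantom("water_box", (40, 40, 40), (2.0, 2.0, 2.0), ptv_radius=4.4)


@pytest.fixture(scope="session")
def water_box_1mm():
    """Case-1-like geometry: 0.36 cc spherical PTV in homogeneous water, 1 mm grid."""
    return clrt.make_phantom("water_box", (48, 48, 48), (1.0, 1.0, 1.0), ptv_radius=4.4)


@pytest.fixture(scope="session")
def lens_a():
    return clrt.builtin_lens("A")


@pytest.fixture(scope="session")
def lens_b():
    return clrt.builtin_lens("B")


def uniform_water_grid(dims, spacing, origin=(0.0, 0.0, 0.0)):
    return clrt.VoxelGrid(np.ones(dims), spacing=spacing, origin=origin)
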