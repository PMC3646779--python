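import numpy as np
import pytest

import fibroquant as fq


@pytest.fixture(scope="session")
def mouse():
    return fq.get_preset("mouse47t")


@pytest.fixture(scope="session")
def rat():
    return fq.get_preset("rat47t")


@pytest.fixture
def small_geometry():
    """A small geometry for fast I/O and pipeline tests."""
    return fq.ImageGeometry(matrix_size=64, field_of_view_mm=10.0,
                            slice_thickness_mm=1.0, n_slices=4)


@pytest.fixture
def small_stack(small_geometry):
    rng = np.random.default_rng(7)
    vox = rng.uniform(0, 100, size=small_geometry.shape)
    return fq.LungStack(voxels=vox, geometry=small_geometry)


def mouse_phantom(lesion_volume_ul: float, seed: int,
                  noise_sigma: float = 16.0):
    """A mouse-geometry phantom with vessels and approximately the requested
    lesion load; lesion/lung contrast is 80, i.e. 5x the default noise."""
    g = fq.get_preset("mouse47t")
    lesions = (fq.dispersed_lesions(g, lesion_volume_ul, seed=seed)
               if lesion_volume_ul > 0 else ())
    spec = fq.PhantomSpec(geometry=g, vessels=fq.default_vessels(g),
                          lesions=lesions, noise_sigma=noise_sigma, seed=seed)
    return fq.generate_lung_phantom(spec)
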