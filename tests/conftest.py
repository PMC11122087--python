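import numpy as np
import pytest

import msct_cp as mc
from msct_cp.model import SpectralModel


@pytest.fixture(scope="session")
def geom8():
    """8x8 unit-FOV geometry with 10 angles and 12 detector bins."""
    angles = tuple(np.arange(10) * np.pi / 10)
    return mc.Geometry(
        n_pixels_side=8, angles=angles, n_detector_bins=12,
        pixel_size=1 / 8, detector_spacing=1 / 8,
    )


@pytest.fixture(scope="session")
def proj8(geom8):
    return mc.build_projector(geom8)


@pytest.fixture(scope="session")
def model_small():
    """Spectral model at desk dimensions M=3, B=5 on a coarse 12-node grid."""
    return mc.make_spectral_model(M=3, B=5, E=12, e_max=150.0, seed=1)


@pytest.fixture(scope="session")
def toy_model():
    """Scalar-checkable instance: E=2, M=1, B=1, S=[[1,1]], attenuations (1,3)."""
    return SpectralModel(
        energies=[30.0, 90.0],
        attenuations=[[1.0], [3.0]],
        spectra=[[1.0, 1.0]],
    )


@pytest.fixture(scope="session")
def proj64():
    return mc.build_projector(mc.default_geometry(64))


@pytest.fixture(scope="session")
def model64():
    """Reconstruction-grid model for the standard 64x64 experiment (E=20)."""
    return mc.make_spectral_model(M=3, B=5, E=20, e_max=150.0, seed=1)


@pytest.fixture(scope="session")
def truth64():
    return mc.make_phantom(mc.default_phantom_spec(64), seed=0)


def random_image(rng, n_pixels, M, scale=0.5):
    return scale * rng.random((n_pixels, M))
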