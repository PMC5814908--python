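import numpy as np
import pytest

from epighost import (
    AcquisitionParams,
    EpiKspace,
    ImageGrid,
    PhantomSpec,
    PhaseCoeffs,
    RoiSet,
    build_ghost_bands,
    make_phantom,
)
from epighost.model import image_to_kspace


def full_kspace(img: ImageGrid, echo_spacing: float = 552e-6) -> EpiKspace:
    """Fully sampled k-space of an image (no corruption)."""
    n_pe = img.data.shape[1]
    return EpiKspace(
        data=image_to_kspace(img.data),
        echo_spacing=echo_spacing,
        acquired_mask=np.ones(n_pe, dtype=bool),
        lines_before_center=n_pe // 2,
    )


def random_image(seed: int, shape=(32, 32)) -> ImageGrid:
    rng = np.random.default_rng(seed)
    return ImageGrid(rng.standard_normal(shape) + 1j * rng.standard_normal(shape))


@pytest.fixture
def disk():
    """Centred disk phantom of radius half the FOV on a 32x32 grid."""
    return make_phantom(PhantomSpec.disk(0.5))


@pytest.fixture
def disk_mask(disk):
    return disk.magnitude > 0


@pytest.fixture
def disk_rois(disk_mask):
    return RoiSet.from_object_mask(disk_mask)


@pytest.fixture
def disk_bands(disk_mask):
    return build_ghost_bands(disk_mask)


@pytest.fixture
def noiseless_params():
    return AcquisitionParams(coeffs=PhaseCoeffs(0.3, 0.05), noise_sd=0.0)
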