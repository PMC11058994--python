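import numpy as np
import pytest

from htseg import (
    BinaryMask,
    BrainMask,
    CTVolume,
    PhantomSpec,
    ROIBox,
    make_head_phantom,
)

SPACING = (5.0, 0.5, 0.5)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and blur-free phantom: region statistics are as drawn."""
    spec = PhantomSpec(
        shape=(16, 96, 96), lesion_target_ml=8.0, noise_sd=0.0, blur_sigma=0.0, seed=42
    )
    return make_head_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default acquisition conditions (blur sigma 1, noise SD 2)."""
    return make_head_phantom(PhantomSpec(shape=(16, 96, 96), lesion_target_ml=8.0, seed=42))


def flat_volume(shape=(4, 16, 16), value=30.0, spacing=SPACING) -> CTVolume:
    return CTVolume(np.full(shape, value, dtype=np.float32), spacing)


def full_brain(vol: CTVolume) -> BrainMask:
    return BrainMask(
        mask=BinaryMask(np.ones(vol.shape, dtype=bool), vol.spacing), provenance="test"
    )


def full_roi(vol: CTVolume) -> ROIBox:
    return ROIBox(0, vol.shape[0], 0, vol.shape[1], 0, vol.shape[2])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
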