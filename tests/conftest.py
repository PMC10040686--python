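import numpy as np
import pytest

from rpquant import VoxelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return VoxelVolume(np.asarray(values), spacing, origin)


@pytest.fixture
def random_dose_and_masks(rng):
    """Random 20^3 dose grid with a lung mask and a lesion inside it."""
    shape = (20, 20, 20)
    dose = VoxelVolume(rng.uniform(0, 66, size=shape), (2.0, 2.0, 2.5))
    lung = rng.random(shape) < 0.5
    lesion = lung & (rng.random(shape) < 0.3)
    lesion.flat[np.flatnonzero(lung)[0]] = True  # guarantee non-empty
    return (
        dose,
        VoxelVolume(lung.astype(np.uint8), (2.0, 2.0, 2.5)),
        VoxelVolume(lesion.astype(np.uint8), (2.0, 2.0, 2.5)),
    )
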