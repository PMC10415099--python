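import numpy as np
import pytest

from adcseg.phantom import PhantomSpec, generate_case
from adcseg.volume_io import ADC_UNITS, INTENSITY, BinaryMask, ImageVolume

SPACING = (2.0, 2.0, 2.0)


def volume(data, units=INTENSITY, spacing=SPACING):
    return ImageVolume(np.asarray(data, dtype=float), spacing, units)


def adc_volume(data, spacing=SPACING):
    return ImageVolume(np.asarray(data, dtype=float), spacing, ADC_UNITS)


def mask(data, spacing=SPACING):
    return BinaryMask(np.asarray(data, dtype=bool), spacing)


def full_mask(shape, spacing=SPACING):
    return BinaryMask(np.ones(shape, dtype=bool), spacing)


@pytest.fixture(scope="session")
def small_spec():
    """A quick-to-generate phantom whose lesion is large enough to detect."""
    return PhantomSpec(
        grid_shape=(40, 48, 40),
        lesion_radii_vox=(4.5, 5.2, 4.5),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_case(small_spec)


@pytest.fixture(scope="session")
def noisefree_case():
    return generate_case(
        PhantomSpec(grid_shape=(32, 38, 32), lesion_radii_vox=(3.0, 3.4, 3.0),
                    noise_sd=0.0, seed=7)
    )
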