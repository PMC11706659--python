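import numpy as np
import pytest

from stripelum.calibration import calibrate, measure_standard
from stripelum.synthetic import SyntheticImageSpec, generate_fish_image


@pytest.fixture(scope="session")
def image_spec():
    return SyntheticImageSpec(seed=1)


@pytest.fixture(scope="session")
def noise_free_spec():
    return SyntheticImageSpec(noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def synthetic_fish(image_spec):
    return generate_fish_image(image_spec)


@pytest.fixture(scope="session")
def noise_free_fish(noise_free_spec):
    return generate_fish_image(noise_free_spec)


def calibrated_from(spec, image):
    std = measure_standard(
        image, spec.standard_rect, reflectance=spec.standard_reflectance
    )
    return calibrate(image, std, px_per_mm=spec.px_per_mm)


@pytest.fixture(scope="session")
def calibrated_fish(image_spec, synthetic_fish):
    image, truth = synthetic_fish
    return calibrated_from(image_spec, image), truth


@pytest.fixture(scope="session")
def calibrated_noise_free(noise_free_spec, noise_free_fish):
    image, truth = noise_free_fish
    return calibrated_from(noise_free_spec, image), truth
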