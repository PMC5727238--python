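import numpy as np
import pytest

from dectmap import (
    CompartmentParams,
    NoiseSpec,
    OrganPhantomSpec,
    synthetic_calibration_i2e,
)


@pytest.fixture(scope="session")
def calset():
    return synthetic_calibration_i2e()


@pytest.fixture
def small_organ_spec():
    """48^3 organ phantom with stain-concentrating heart (cap 1.3)."""
    return OrganPhantomSpec(
        shape=(48, 48, 48),
        center=(23.5, 23.5, 23.5),
        semiaxes=(19.0, 16.0, 14.0),
        heart_split_offset=-3.0,
        container_inner_radius=19.0,
        container_wall=2.0,
    )


@pytest.fixture
def unit_cap_spec(small_organ_spec):
    """Same geometry but with stain fractions capped at 1 (truth sums to 1)."""
    from dataclasses import replace

    return replace(
        small_organ_spec,
        compartments={
            "heart": CompartmentParams(diffusivity=1.0, f_surface=1.0, f_max=1.0),
            "lung": CompartmentParams(diffusivity=0.35, f_surface=1.0, f_max=1.0),
        },
    )


@pytest.fixture
def quiet_noise():
    return NoiseSpec(sigma=0.0, beta=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
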