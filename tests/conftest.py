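import numpy as np
import pytest

from t2contrast import (
    AcquisitionSpec,
    TissueSpec,
    build_geometry,
    fit_t2_loglinear,
    simulate_echo_train,
)

# Study-emulating tissue pair used throughout: GM-like T2 90 ms, WM-like 70 ms.
GM = TissueSpec("GM", proton_density=1000.0, t2_ms=90.0, t2_age_slope=0.0)
WM = TissueSpec("WM", proton_density=1000.0, t2_ms=70.0, t2_age_slope=0.0)


@pytest.fixture(scope="session")
def geometry16():
    return build_geometry((16, 16, 16), (1.0, 1.0, 1.0), "two_compartment")


@pytest.fixture(scope="session")
def tissues():
    return {1: GM, 2: WM}


@pytest.fixture(scope="session")
def clean_acquisition():
    """Noiseless, bias-free, uncontaminated 10-echo train."""
    return AcquisitionSpec(noise_sigma=0.0, bias_amplitude=0.0, first_echo_gain=1.0)


@pytest.fixture(scope="session")
def clean_volume(geometry16, tissues, clean_acquisition):
    vol, truth = simulate_echo_train(geometry16, tissues, clean_acquisition, seed=0)
    return vol, truth


@pytest.fixture(scope="session")
def clean_t2map(clean_volume):
    vol, _ = clean_volume
    return fit_t2_loglinear(vol)


@pytest.fixture(scope="session")
def sphere_mask():
    xx, yy, zz = np.mgrid[:24, :24, :24]
    return (xx - 12) ** 2 + (yy - 12) ** 2 + (zz - 12) ** 2 <= 8**2
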