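import numpy as np
import pytest

from guanoptics import tmm


@pytest.fixture(scope="session")
def optics():
    return tmm.OpticalConstants()


@pytest.fixture(scope="session")
def mean_stack():
    """Mean-geometry C. annae stack: 6 platelets of 53 nm, 5 gaps of 70 nm."""
    return tmm.StackGeometry((53.0,) * 6, (70.0,) * 5)


@pytest.fixture(scope="session")
def wavelengths():
    return tmm.default_wavelengths()


@pytest.fixture(scope="session")
def mean_stack_spectrum(mean_stack, optics, wavelengths):
    return tmm.stack_reflectance(mean_stack, optics, wavelengths)


@pytest.fixture(scope="session")
def small_population():
    from guanoptics import structures

    return structures.sample_stack_population("c_annae", 30, 42)
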