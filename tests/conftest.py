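import numpy as np
import pytest

from beamopt import Domain, RadiationParams
from beamopt.tables import reference_fermi, reference_gaussian


@pytest.fixture(scope="session")
def radiation():
    """Reference radiation constants: gamma=60/day, dt=0.007 day, C=2.5, F'=25."""
    return RadiationParams()


@pytest.fixture(scope="session")
def domain():
    return Domain()


@pytest.fixture(scope="session")
def gauss3():
    """Reference Gaussian tumour, sigma=3 mm, ~1e7 cells."""
    return reference_gaussian(3.0)


@pytest.fixture(scope="session")
def gauss1():
    return reference_gaussian(1.0)


@pytest.fixture(scope="session")
def fermi1():
    """Fermi density fitted to the sigma=1 logistic-growth profile."""
    return reference_fermi(1.0)


def round_sig(x, n=3):
    """Round to n significant figures (for table comparisons)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (n - 1))
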