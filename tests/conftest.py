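import numpy as np
import pytest

from catia.bank import load_packaged_bank
from catia.grm import QuadratureGrid
from catia.synthetic import SyntheticDesign, generate_bank, generate_population, generate_responses


@pytest.fixture(scope="session")
def packaged_bank():
    return load_packaged_bank()


@pytest.fixture(scope="session")
def grid():
    return QuadratureGrid.normal()


@pytest.fixture(scope="session")
def fine_grid():
    """Brute-force 10,001-point grid used as the EAP integration oracle.

    Same [-4, 4] prior support as the default grid; only the resolution
    differs, so agreement isolates quadrature error.
    """
    return QuadratureGrid.normal(10001, 4.0)


@pytest.fixture(scope="session")
def clean_design():
    return SyntheticDesign(n_persons=1000, n_items=20, seed=11)


@pytest.fixture(scope="session")
def clean_bank(clean_design):
    return generate_bank(clean_design)


@pytest.fixture(scope="session")
def clean_responses(clean_design, clean_bank):
    pop = generate_population(clean_design)
    return generate_responses(clean_bank, pop, clean_design)
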