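import numpy as np
import pytest

import glbkin as g


@pytest.fixture(scope="session")
def two_heme():
    return g.two_heme()


@pytest.fixture(scope="session")
def one_heme():
    return g.one_heme()


@pytest.fixture(scope="session")
def two_heme_mutant(two_heme):
    return g.no_distal_his(two_heme)


@pytest.fixture
def trap_assay():
    return g.AssayConditions(
        assay_kind="O2_dissociation_trap",
        protein_conc=2.5e-6,
        O2_conc=125e-6,
    )


@pytest.fixture
def nir_assay():
    return g.AssayConditions(
        assay_kind="NiR",
        protein_conc=2.5e-6,
        dithionite_conc=5e-3,
    )


@pytest.fixture
def no_assay():
    return g.AssayConditions(assay_kind="NO_binding", protein_conc=2.5e-6)


DITHIONITE_SERIES = [6.75e-3, 13.5e-3, 27.5e-3]
NITRITE_SERIES = [0.05e-3, 0.1e-3, 0.25e-3, 0.5e-3, 1.0e-3]
NO_SERIES = [10e-6, 20e-6, 40e-6, 80e-6, 160e-6]


@pytest.fixture(scope="session")
def one_heme_trap_instrument():
    return g.scanning_spectrophotometer(duration=25.0, sampling=0.2)


@pytest.fixture(scope="session")
def two_heme_trap_instrument():
    # dense sampling: separating a 1.68-fold rate pair needs ~600 points
    return g.scanning_spectrophotometer(duration=30.0, sampling=0.05)
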