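import numpy as np
import pytest

from fdcdiff import chem_data as cd


@pytest.fixture(scope="session")
def fixture_panel():
    """All catalog molecules in heavy-atom form."""
    return cd.fixture_panel()


@pytest.fixture(scope="session")
def ethanol_complex():
    """Deterministic toy complex around the ethanol template."""
    return cd.make_toy_complex(cd.ToyComplexSpec("ethanol", seed=1))


@pytest.fixture(scope="session")
def anisole_complex():
    return cd.make_toy_complex(
        cd.ToyComplexSpec("methyl_phenyl_ether", seed=2)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
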