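import pandas as pd
import pytest

from urbes import Compartment, rbc_fixture


@pytest.fixture(scope="session")
def rbc():
    """Reference-study bundle and its expected score matrix."""
    return rbc_fixture()


@pytest.fixture()
def small_survey():
    """Two plots in one compartment, three species."""
    return pd.DataFrame(
        {
            "plot_id": ["p1", "p1", "p1", "p2", "p2"],
            "compartment_id": ["C1"] * 5,
            "species": ["quercus ilex", "hedera helix", "ruscus aculeatus", "quercus ilex", "hedera helix"],
            "bb": ["3", "1", "+", "5", "2"],
        }
    )


@pytest.fixture()
def forest_compartment():
    return Compartment("C1", "forest", "managed", area_ha=1.0)
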