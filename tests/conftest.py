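import numpy as np
import pytest

from metallospec import (
    Component,
    EquilibriumModel,
    SpeciesDef,
    fixture_model,
)


@pytest.fixture(scope="session")
def gmt_model_25():
    return fixture_model("gmt_acid_base_25C")


@pytest.fixture(scope="session")
def gmt_model_37():
    return fixture_model("gmt_acid_base_37C")


@pytest.fixture(scope="session")
def mn_model_45():
    return fixture_model("mn_gmt_45C")


@pytest.fixture(scope="session")
def zn_model_45():
    return fixture_model("zn_gmt_45C")


@pytest.fixture(scope="session")
def strong_acid_model():
    """Water autoprotolysis only."""
    return EquilibriumModel(
        components=[Component("H", 1)], species=[], pKw=13.97, temperature=298.15
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240913)
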