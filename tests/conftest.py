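import pytest

from scfaquant.registry import load_panel
from scfaquant.simulate import PeakShapeParams, default_is_concentrations


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def shape(panel):
    return PeakShapeParams.defaults_for_panel(panel)


@pytest.fixture(scope="session")
def is_mix(panel):
    return default_is_concentrations(panel)


# Table-of-record values the transition chemistry must reproduce:
# name -> (RT min, nominal precursor, quantifier, qualifier or None)
REFERENCE_TABLE = {
    "acetic acid": (1.15, 151, 109, 133),
    "lactic acid": (1.28, 181, 109, 92),
    "propionic acid": (1.85, 165, 109, 92),
    "isobutyric acid": (3.11, 179, 109, 161),
    "succinic acid": (3.26, 299, 191, 109),
    "butyric acid": (3.32, 179, 109, 92),
    "2-methylbutyric acid": (5.03, 193, 109, 175),
    "isovaleric acid": (5.50, 193, 109, 175),
    "valeric acid": (6.08, 193, 109, 175),
    "2,2-dimethylbutyric acid": (8.10, 207, 109, 92),
    "indole-3-acetic acid": (8.18, 266, 109, None),
    "indole-3-lactic acid": (8.23, 296, 109, None),
    "2-methylvaleric acid": (8.25, 207, 109, None),
    "3-methylvaleric acid": (8.59, 207, 109, None),
    "4-methylvaleric acid": (9.20, 207, 109, None),
    "indole-3-propionic acid": (9.51, 280, 201, 109),
    "caproic acid": (9.88, 207, 109, 99),
    "indole-3-butyric acid": (11.87, 294, 109, None),
    "d4-acetic acid": (1.11, 154, 110, 92),
    "2-ethylbutyric acid": (7.26, 207, 109, 71),
    "d2-indole-3-propionic acid": (9.45, 282, 130, 110),
}


@pytest.fixture(scope="session")
def reference_table():
    return REFERENCE_TABLE
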