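import numpy as np
import pytest

from dosidensity.tissue_optics import ExtinctionTable, FDGeometry, TissueComposition


@pytest.fixture(scope="session")
def table() -> ExtinctionTable:
    return ExtinctionTable.default()


@pytest.fixture(scope="session")
def geometry() -> FDGeometry:
    return FDGeometry()


@pytest.fixture
def typical_composition() -> TissueComposition:
    # healthy-breast scale values: ~5 uM ctHHb, ~18 uM ctO2Hb, ~21% water,
    # ~70% lipid
    return TissueComposition(ct_hhb=5.0, ct_o2hb=18.0, water=21.4, lipid=69.7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
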