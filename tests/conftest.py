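import numpy as np
import pandas as pd
import pytest

from imctme.io import CellTable, Marker, PanelDefinition, RoiGeometry


@pytest.fixture
def toy_panel() -> PanelDefinition:
    return PanelDefinition((Marker("CD68", "immune", "Pt198"),
                            Marker("S100B", "neoplastic", "Pr141")))


@pytest.fixture
def toy_geometry() -> list[RoiGeometry]:
    return [RoiGeometry("r1", "c1", 1000.0, 1000.0),
            RoiGeometry("r2", "c1", 500.0, 1000.0)]


@pytest.fixture
def toy_table() -> CellTable:
    obs = pd.DataFrame({
        "cell_id": ["a", "b", "c"],
        "case_id": ["c1", "c1", "c1"],
        "roi_id": ["r1", "r1", "r2"],
        "x_um": [10.0, 500.0, 100.0],
        "y_um": [20.0, 600.0, 900.0]})
    raw = pd.DataFrame({"CD68": [1.0, 2.0, 3.0], "S100B": [0.5, 0.0, 4.0]})
    return CellTable(obs=obs, raw=raw)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
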