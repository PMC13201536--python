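import numpy as np
import pandas as pd
import pytest

from skinarch.preprocess import NormalizedMatrix
from skinarch.synth import TissueConfig, VesselSpec, generate_tissue


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_norm(values, features=None, cell_ids=None, method="zscore"):
    values = np.asarray(values, dtype=float)
    if features is None:
        features = [f"g{j}" for j in range(values.shape[1])]
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(values, list(features), list(cell_ids), method, {})


@pytest.fixture
def small_tissue():
    """A small but complete tissue: epidermis, both dermal zones, one vessel."""
    config = TissueConfig(
        width_um=1000.0,
        height_um=400.0,
        papilla_amplitude_um=15.0,
        papilla_period_um=200.0,
        epidermis_thickness_um=50.0,
        cells_per_type={
            "epidermis": {"keratinocyte": 300},
            "papillary": {"fibroblast": 150, "immune": 50},
            "reticular": {"fibroblast": 200, "immune": 50},
        },
        vessel_specs=[VesselSpec(8, (500.0, 110.0), 90.0, 50.0)],
        marker_log2fc={
            ("fibroblast", "COL1A1"): 3.0,
            ("fibroblast", "PDGFRA"): 3.0,
            ("fibroblast", "LUM"): 3.0,
            ("immune", "PTPRC"): 3.0,
            ("immune", "CD3E"): 3.0,
            ("immune", "CD68"): 3.0,
        },
        treatment_log2fc={"RESP1": 1.0, "RESP2": 1.0, "RESP3": -1.0},
        seed=11,
    )
    return config, generate_tissue(config)


@pytest.fixture
def cell_frame():
    """Tiny hand-positioned cell table."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "sample": ["s1"] * 6,
            "timepoint": ["baseline"] * 6,
            "x_um": [0.0, 10.0, 20.0, 0.0, 10.0, 500.0],
            "y_um": [0.0, 0.0, 0.0, 100.0, 100.0, 300.0],
            "area_um2": [50.0] * 6,
            "true_type": ["keratinocyte"] * 3 + ["fibroblast"] * 3,
        }
    )
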