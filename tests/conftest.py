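import numpy as np
import pandas as pd
import pytest

from nichecord.datatypes import GeneExpressionMatrix
from nichecord.io_core import normalize_log
from nichecord import synthetic_data as sd


def make_matrix(counts, genes=None, cells=None, norm=False) -> GeneExpressionMatrix:
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{j}" for j in range(counts.shape[1])]
    m = GeneExpressionMatrix(genes, cells, counts)
    return normalize_log(m) if norm else m


@pytest.fixture(scope="session")
def breast_dataset() -> sd.SyntheticDataset:
    return sd.generate_dataset(sd.scenario_presets("breast_like", seed=0))


@pytest.fixture(scope="session")
def two_region_config() -> sd.SyntheticConfig:
    """Small two-region, four-type scenario with disjoint compositions."""
    return sd.SyntheticConfig(
        cell_types=("t1", "t2", "t3", "t4"),
        cells_per_type=75,
        n_genes=400,
        grid=(8, 8),
        regions=(
            sd.Region("west", (0, 8), (0, 4), {"t1": 1, "t2": 1, "t3": 0, "t4": 0}),
            sd.Region("east", (0, 8), (4, 8), {"t1": 0, "t2": 0, "t3": 1, "t4": 1}),
        ),
        cells_per_spot_range=(1, 6),
        nb_dispersion=50.0,
        signature_strength=3.0,
        lr_truth=(),
        n_lr_background=4,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
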