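import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from quantbiome.io import CountTable
from quantbiome.quantify import AbundanceMatrix
from quantbiome.synthetic import study_config, generate_experiment


@pytest.fixture
def toy_counts() -> CountTable:
    counts = pd.DataFrame(
        {"s1": [3, 1, 0], "s2": [10, 0, 10]},
        index=["OTU001", "OTU002", "OTU003"],
    )
    taxonomy = pd.Series(
        {
            "OTU001": "d__Bacteria;p__B;c__C;o__O;f__Lachnospiraceae;g__G;s__s1",
            "OTU002": "d__Bacteria;p__B;c__C;o__O;f__Bacteroidaceae;g__G;s__s2",
            "OTU003": "d__Bacteria;p__B;c__C;o__O;f__Lachnospiraceae;g__G;s__s3",
        }
    )
    return CountTable(counts=counts, taxonomy=taxonomy)


@pytest.fixture
def toy_densities() -> pd.Series:
    return pd.Series({"s1": 1.0e9, "s2": 2.0e9}, name="total_cells_per_ml")


def make_matrix(values: dict, lods: dict) -> AbundanceMatrix:
    cells = pd.DataFrame(values)
    return AbundanceMatrix(
        cells_per_ml=cells, lod_cells_per_ml=pd.Series(lods, dtype=float)
    )


@pytest.fixture(scope="session")
def study_experiment():
    """A small study-emulating run: 6 donors x 3 conditions, 100 taxa."""
    return generate_experiment(study_config(seed=11, n_taxa=100))
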