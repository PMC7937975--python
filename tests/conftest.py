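from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from petalpath.io import load_substitution_matrix
from petalpath.simulate import SimulationConfig

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def deg_panel_table():
    """The published candidate-panel DEG table (TMM pairs, log-FC, category)."""
    return pd.read_csv(DATA / "deg_panel_table.tsv", sep="\t")


@pytest.fixture(scope="session")
def panel_degs(deg_panel_table):
    """The panel table reshaped into the screen's DEG-record layout."""
    df = deg_panel_table
    return pd.DataFrame({
        "gene_id": df["gene_id"],
        "mean_tmm_blue": df["tmm_blue"],
        "mean_tmm_orange": df["tmm_orange"],
        "log2fc": df["log_fold_change"],
        "p_value": 0.0,
        "fdr": 0.0,
        "is_deg": True,
        "direction": np.where(df["log_fold_change"] > 0, "B>O", "O>B"),
        "category": df["category"],
    })


@pytest.fixture
def sample_sheet():
    cfg = SimulationConfig(seed=0, n_per_group=4)
    return cfg.sample_sheet()


@pytest.fixture
def small_config():
    """Small but fully featured simulation for fast end-to-end tests."""
    return SimulationConfig(seed=11, n_genes=60,
                            library_size_range=(30_000, 60_000))
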