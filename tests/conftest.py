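import numpy as np
import pandas as pd
import pytest

from foramsize import EventSimulationParams, generate_genus_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_event_table():
    """A tiny hand-built genus table with both outcome classes."""
    return pd.DataFrame(
        {
            "genus": [f"g{i}" for i in range(8)],
            "event": "P-T",
            "mean_log10_volume": [6.8, 7.0, 7.2, 7.5, 7.6, 7.8, 8.0, 8.2],
            "sd_log10_volume": 0.2,
            "n_specimens": 5,
            "species_richness": [1, 2, 1, 3, 2, 1, 4, 2],
            "range_cells": [2, 3, 1, 4, 2, 5, 3, 2],
            "status": [0, 0, 0, 0, 1, 1, 1, 1],
            "size_class": ["small"] * 3 + ["large"] * 5,
        }
    )


@pytest.fixture
def synthetic_table():
    """Moderately sized simulated event table with known selectivity."""
    params = EventSimulationParams(
        "P-T", n_genera=400, size_mean=7.5, size_sd=0.8, beta0=0.0,
        beta_size=1.2, seed=42,
    )
    return generate_genus_table(params)
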