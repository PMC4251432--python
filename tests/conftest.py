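"""Shared fixtures: hand-built genealogies and small simulation runs."""

import numpy as np
import pandas as pd
import pytest

from latdiv import preset, run_simulation
from latdiv.config import ScenarioConfig


def species_frame(rows):
    """Build a species table from (species_id, parent_id, origin, extinction, trait)."""
    return pd.DataFrame(
        rows, columns=["species_id", "parent_id", "origin_time", "extinction_time", "trait"]
    )


@pytest.fixture
def chain_species():
    """A budding chain 1 -> 2 -> 3, all extant."""
    return species_frame(
        [
            (1, 0, 0, -1, 40.0),
            (2, 1, 20, -1, 39.0),
            (3, 2, 60, -1, 38.0),
        ]
    )


@pytest.fixture
def small_config():
    """A tiny, fast scenario for exercising the full run machinery."""
    return ScenarioConfig(
        n_regions=5,
        env_values=(40.0, 30.0, 20.0, 10.0, 0.0),
        sigma_E=1.0,
        omega=3.0,
        K=(2000.0,) * 5,
        p_speciation=(5e-5,) * 5,
        p_dispersal=1e-3,
        alpha_ext=0.01,
        zero_sum=True,
        origin_region=1,
        max_steps=400,
        max_species=10_000,
        snapshot_interval=100,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_run():
    """One modest zero-sum run reused by several structural tests."""
    cfg = ScenarioConfig(
        n_regions=5,
        env_values=(40.0, 30.0, 20.0, 10.0, 0.0),
        K=(2000.0,) * 5,
        p_speciation=(5e-5,) * 5,
        p_dispersal=1e-3,
        alpha_ext=0.01,
        zero_sum=True,
        origin_region=1,
        max_steps=600,
        max_species=10_000,
        snapshot_interval=200,
        seed=7,
    )
    return run_simulation(cfg)
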