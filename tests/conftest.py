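import numpy as np
import pandas as pd
import pytest

from arrestmap.integration import apply_matched_normalization, fit_control_stats
from arrestmap.io import FeatureTable
from arrestmap.simulate import PopulationSimConfig, simulate_population


@pytest.fixture(scope="session")
def small_population() -> FeatureTable:
    """1,500-cell default-mix population at the default noise level."""
    return simulate_population(PopulationSimConfig(n_cells=1500, seed=11))


@pytest.fixture(scope="session")
def noiseless_population() -> FeatureTable:
    """Zero-noise population: every feature equals its mean function."""
    return simulate_population(
        PopulationSimConfig(n_cells=1200, noise_cv=0.0, seed=5)
    )


@pytest.fixture(scope="session")
def normalized_population(small_population) -> FeatureTable:
    params = fit_control_stats(small_population, "control")
    return apply_matched_normalization(small_population, params)


@pytest.fixture()
def tiny_table() -> FeatureTable:
    """Hand-written 3-cell table with two features."""
    return FeatureTable(
        pd.DataFrame(
            {
                "cell_id": ["c1", "c2", "c3"],
                "condition": ["control", "control", "etoposide_d3"],
                "replicate": ["r1", "r1", "r1"],
                "p21_nucleus_median": [1.0, 2.0, 3.0],
                "dna_nucleus_integrated": [100.0, 1e-12, 200.0],
            }
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
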