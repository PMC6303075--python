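"""Shared fixtures: small synthetic diallels and hand-built tables."""

import numpy as np
import pandas as pd
import pytest

from sexdiallel import DiallelDataset, SimulationConfig, generate_diallel


@pytest.fixture(scope="session")
def toy3_df():
    """3-strain diallel, one record per family x sex (18 rows)."""
    rows = []
    for dam in (1, 2, 3):
        for sire in (1, 2, 3):
            for sex, base in (("F", 20), ("M", 30)):
                rows.append((dam, sire, sex, 1, base + dam * 3 + sire))
    return pd.DataFrame(rows, columns=["dam", "sire", "sex", "block",
                                       "fitness"])


@pytest.fixture(scope="session")
def toy3_ds(toy3_df):
    return DiallelDataset(toy3_df, n_strains=3)


@pytest.fixture(scope="session")
def balanced4_ds():
    """Complete 4x4 diallel, both sexes, two blocks, two replicates."""
    rng = np.random.default_rng(42)
    rows = []
    for dam in range(1, 5):
        for sire in range(1, 5):
            for sex in ("F", "M"):
                for block in (1, 2):
                    for _ in range(2):
                        rows.append((dam, sire, sex, block,
                                     int(rng.integers(20, 60))))
    return DiallelDataset(pd.DataFrame(
        rows, columns=["dam", "sire", "sex", "block", "fitness"]),
        n_strains=4)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic diallel (full reversal world)."""
    ds, truth = generate_diallel(SimulationConfig(seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def small_sim():
    """8-strain simulated diallel: cheap enough for repeated REML fits."""
    cfg = SimulationConfig(seed=5, n_strains=8, replicates=2,
                           missingness=0.0)
    ds, truth = generate_diallel(cfg)
    return ds, truth
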