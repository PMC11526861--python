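import numpy as np
import pandas as pd
import pytest

from nucbench.contact_core import BinTable, ContactMatrix, balance_ic
from nucbench.genome_model import (
    GroundTruth,
    SimulationConfig,
    build_expected_matrix,
    sample_contacts,
)


@pytest.fixture(scope="session")
def decay_only_config():
    """Pure power-law decay: no plaid, no boundaries, no loops."""
    return SimulationConfig(seed=11, loop_count=0, delta=0.0, gamma=1.0, block_length_mean=10**9)


@pytest.fixture(scope="session")
def decay_only_deep(decay_only_config):
    """Balanced matrix sampled at high depth from the pure-decay model."""
    expected, truth = build_expected_matrix(decay_only_config)
    matrix = balance_ic(sample_contacts(expected, 10_000_000, seed=12))
    return expected, truth, matrix


@pytest.fixture(scope="session")
def plaid_sim():
    """Structured simulation (plaid + boundaries, no loops), deep sampling."""
    cfg = SimulationConfig(seed=21, loop_count=0)
    expected, truth = build_expected_matrix(cfg)
    matrix = balance_ic(sample_contacts(expected, 10_000_000, seed=22))
    return cfg, expected, truth, matrix


@pytest.fixture(scope="session")
def equal_blocks_truth():
    """Hand-planted alternating A/B blocks of exactly equal total size."""
    cfg = SimulationConfig(seed=0, loop_count=0, gamma=1.0, delta=1.0)
    bt = cfg.bin_table
    labels = np.array((["A"] * 100 + ["B"] * 100) * 2)
    truth = GroundTruth(
        bt,
        labels,
        np.array([100, 200, 300]),
        pd.DataFrame(columns=["bin1", "bin2", "beta", "kind"]),
        pd.DataFrame(columns=["gene", "promoter_bin", "enhancer_bin"]),
    )
    return cfg, truth


@pytest.fixture()
def toy_matrix_6():
    """Printed 6-bin single-chromosome fixture with unit weights."""
    bt = BinTable({"chrT": 6 * 10}, 10)
    # upper-triangle counts, row-major: (0,0)..(0,5),(1,1)..,(5,5)
    pix = [
        (0, 0, 4), (0, 1, 3), (0, 2, 7), (0, 3, 1), (0, 4, 2), (0, 5, 5),
        (1, 1, 6), (1, 2, 2), (1, 3, 8), (1, 4, 3), (1, 5, 1),
        (2, 2, 5), (2, 3, 4), (2, 4, 6), (2, 5, 2),
        (3, 3, 7), (3, 4, 1), (3, 5, 3),
        (4, 4, 2), (4, 5, 9),
        (5, 5, 4),
    ]
    b1, b2, c = map(np.array, zip(*pix))
    m = ContactMatrix(bt, b1, b2, c.astype(float))
    m.weights = np.ones(6)
    return m
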