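import numpy as np
import pandas as pd
import pytest

from proxipipe import (
    SpectralCountTable,
    compute_bfdr,
    default_count_scenario,
    score_interactions,
    simulate_bioid_counts,
)
from proxipipe.counts import COLUMNS


def make_table(rows):
    return SpectralCountTable.from_frame(pd.DataFrame(rows, columns=list(COLUMNS)))


@pytest.fixture
def small_table():
    """Two WT runs, two mutant runs, two control runs; a handful of preys."""
    rows = []
    wt = {"NHERF1": [12, 10], "GOPC": [8, 9], "HSPA8": [6, 5]}
    mut = {"HSPA8": [14, 15], "BAG5": [9, 8]}
    ctl = {"HSPA8": [5, 6]}
    for prey, counts in wt.items():
        for i, c in enumerate(counts):
            rows.append((f"wt_{i + 1}", "CFTR", "WT", i + 1, prey, c))
    for prey, counts in mut.items():
        for i, c in enumerate(counts):
            rows.append((f"mut_{i + 1}", "CFTR", "dF508", i + 1, prey, c))
    for prey, counts in ctl.items():
        for i, c in enumerate(counts):
            rows.append((f"ctl_{i + 1}", "BIRA", "control", i + 1, prey, c))
    return make_table(rows)


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the default planted scenario, shared across tests."""
    cfg = default_count_scenario(seed=0)
    table, truth = simulate_bioid_counts(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def default_scored(default_sim):
    """BFDR-scored interactions per condition for the default scenario."""
    cfg, table, _ = default_sim
    return {
        cond: compute_bfdr(score_interactions(table, cond))
        for cond in cfg.bait_self_count
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
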