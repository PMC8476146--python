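import numpy as np
import pandas as pd
import pytest

import fluxsel as fx


@pytest.fixture(scope="session")
def scenario():
    """Full-size synthetic study (4,000 genotypes, 3 conditions, triplicate)."""
    table, truth = fx.study_scenario(seed=20210616)
    return table, truth


@pytest.fixture(scope="session")
def abundance(scenario):
    table, _ = scenario
    return fx.process_counts(table)


@pytest.fixture(scope="session")
def triplicate_design():
    """Sample grid of one condition: 11 times x 3 replicates (long format)."""
    times = np.array(sorted(list(range(0, 241, 24)) * 3), dtype=float)
    reps = np.tile([1, 2, 3], 11)
    design = pd.DataFrame(
        {"condition": "cond", "replicate": reps, "time": times},
        index=[f"s{i:02d}" for i in range(len(times))],
    )
    return design


class FitInput:
    """Minimal log-abundance container accepted by fit_genotypes."""

    def __init__(self, log: pd.DataFrame, design: pd.DataFrame):
        self.log = log
        self.design = design

    def samples_for(self, condition, replicate=None):
        d = self.design
        mask = d["condition"] == condition
        if replicate is not None:
            mask &= d["replicate"] == replicate
        idx = d.index[mask]
        return idx[np.argsort(d.loc[idx, "time"].to_numpy(), kind="stable")]


@pytest.fixture
def fit_input(triplicate_design):
    def _make(rows: np.ndarray) -> FitInput:
        log = pd.DataFrame(np.atleast_2d(rows), columns=triplicate_design.index)
        return FitInput(log, triplicate_design)

    return _make


def toy_count_table(counts: np.ndarray, times=None, condition="cond", replicate=1,
                    genotypes=None) -> fx.CountTable:
    """Single-replicate count table from a genotypes x times array."""
    counts = np.atleast_2d(counts)
    n_g, n_t = counts.shape
    times = list(times) if times is not None else list(range(n_t))
    design = pd.DataFrame(
        {
            "condition": condition,
            "replicate": replicate,
            "time": [float(t) for t in times],
            "depth": counts.sum(axis=0),
        },
        index=[f"{condition}_r{replicate}_t{i}" for i in range(n_t)],
    )
    design.index.name = "sample_id"
    idx = genotypes if genotypes is not None else [f"g{i}" for i in range(n_g)]
    df = pd.DataFrame(counts, index=pd.Index(idx, name="genotype_id"),
                      columns=design.index)
    return fx.CountTable(df, design)
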