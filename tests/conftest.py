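import numpy as np
import pandas as pd
import pytest

import mirstates as ms


@pytest.fixture(scope="session")
def config():
    return ms.AnalysisConfig()


@pytest.fixture(scope="session")
def planted_dataset():
    """Default 24-sample (8 normal + 16 tumor) dataset, 50 planted pairs."""
    params = ms.SimulationParams()
    return ms.generate_dataset(params)


@pytest.fixture(scope="session")
def planted_result(planted_dataset, config):
    mirna, mrna, pg_map, catalog, groups, truth = planted_dataset
    result = ms.derive_interaction_states(mirna, mrna, pg_map, catalog, config)
    return ms.rank_differential(result, groups), truth, groups


@pytest.fixture()
def toy_states():
    """Hand-written interaction-state table: 8 samples, 2 groups of 4."""
    index = pd.MultiIndex.from_tuples(
        [("mir-a", "g1"), ("mir-b", "g2")], names=["mirna_id", "gene_id"]
    )
    samples = [f"s{i}" for i in range(1, 9)]
    table = pd.DataFrame(
        [["HL"] * 4 + ["LH"] * 4, ["MM"] * 8], index=index, columns=samples
    )
    groups = ms.GroupAssignment(pd.Series(["A"] * 4 + ["B"] * 4, index=samples))
    return table, groups
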