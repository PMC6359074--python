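import numpy as np
import pandas as pd
import pytest

import metshift as ms
from metshift.io import AbundanceTable


@pytest.fixture
def toy_table() -> AbundanceTable:
    """3 samples x 4 metabolites with one missing cell."""
    df = pd.DataFrame(
        {
            "metA": [2.0, 4.0, np.nan],
            "metB": [1.0, 1.0, 1.0],
            "metC": [1.0, np.nan, 8.0],
            "metD": [5.0, 6.0, 7.0],
        },
        index=["s1", "s2", "s3"],
    )
    # keep metC example intact: {1.0, missing, 8.0}
    df.loc["s2", "metC"] = np.nan
    df.loc["s3", "metA"] = np.nan
    return AbundanceTable(df)


def gaussian_table(
    graph: ms.UndirectedNetwork,
    names: list[str],
    n: int,
    seed: int,
    magnitude: float = 0.35,
) -> tuple[AbundanceTable, np.ndarray]:
    """Multivariate-normal table with dependence structure `graph`."""
    omega = ms.graph_to_precision(graph, names, magnitude, seed=seed)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.zeros(len(names)), np.linalg.inv(omega), size=n)
    df = pd.DataFrame(X, index=[f"s{i:04d}" for i in range(n)], columns=names)
    return AbundanceTable(df), omega


def chain_graph(p: int) -> tuple[ms.UndirectedNetwork, list[str]]:
    names = [f"v{i:02d}" for i in range(p)]
    g = ms.UndirectedNetwork.from_edges(
        [(names[i], names[i + 1]) for i in range(p - 1)], nodes=names
    )
    return g, names


@pytest.fixture(scope="session")
def study_scale_run():
    """One synthetic study at the default (study-emulating) conditions."""
    spec = ms.SyntheticSpec(seed=7)
    table, meta, truth = ms.sample_table(spec)
    logged, report = ms.impute_min_and_log(table)
    return spec, table, meta, truth, logged, report
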