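import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import wnes

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def networks():
    return wnes.fixture_networks()


@pytest.fixture(scope="session")
def chain():
    return wnes.DirectedNetwork(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def diamond():
    return wnes.DirectedNetwork(
        ["A", "B", "C", "D"], [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]
    )


def random_dag(rng: np.random.Generator, max_nodes: int = 12) -> wnes.DirectedNetwork:
    """Random DAG on up to max_nodes nodes; edges only go forward in index order."""
    k = int(rng.integers(2, max_nodes + 1))
    labels = [f"N{i}" for i in range(k)]
    edges = [
        (labels[i], labels[j])
        for i in range(k)
        for j in range(i + 1, k)
        if rng.random() < 0.3
    ]
    return wnes.DirectedNetwork(labels, edges)


def group_data(rng: np.random.Generator, n: int, labels, group: str = "D") -> wnes.GroupData:
    frame = pd.DataFrame(rng.normal(size=(n, len(labels))), columns=list(labels))
    return wnes.GroupData(frame, group=group)
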