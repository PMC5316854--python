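import numpy as np
import pandas as pd
import pytest

from hapnet.io import CopyNumberMatrix, DoseSensitivityMap, InteractionSet
from hapnet.network import PathwayNetwork


@pytest.fixture
def toy_gds():
    return DoseSensitivityMap.from_sources(yeast=["B"], mouse=["C"])


@pytest.fixture
def toy_interactions():
    return InteractionSet.from_pairs([("A", "B"), ("B", "X")])


@pytest.fixture
def path_network():
    """A - B - C chain, all GDS 1."""
    return PathwayNetwork(
        name="CHAIN",
        gds={"A": 1, "B": 1, "C": 1},
        edges=(("A", "B"), ("B", "C")),
        mode="intrinsic",
        members=frozenset({"A", "B", "C"}),
    )


def make_matrix(data: dict, samples=None, mode="discrete"):
    df = pd.DataFrame(data).T
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"S{i}" for i in range(df.shape[1])]
    if mode == "discrete":
        df = df.astype(np.int8)
    return CopyNumberMatrix(df, mode=mode)


@pytest.fixture
def chain_matrix():
    """Two samples over the chain genes: one all -1, one mixed."""
    return make_matrix({"A": [-1, -1], "B": [-1, 0], "C": [-1, 1]})
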