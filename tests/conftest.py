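import numpy as np
import pandas as pd
import pytest

import pcpspath.io as pio
from pcpspath import CompositionMatrix, WorldConfig, generate_world


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_tree():
    """((A,B),C) with arbitrary input lengths; normalized to unit branches."""
    return pio.read_tree_string("((A:3.2,B:0.1):5,C:2);")


@pytest.fixture
def toy_W():
    df = pd.DataFrame(
        [[1, 1, 0], [0, 1, 0], [1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
    )
    return CompositionMatrix.from_dataframe(df)


def random_incidence(rng, n_sites=20, n_taxa=50, p=0.4):
    arr = (rng.random((n_sites, n_taxa)) < p).astype(float)
    # ensure no empty rows/columns so validation keeps every taxon
    for j in np.flatnonzero(arr.sum(axis=0) == 0):
        arr[rng.integers(n_sites), j] = 1.0
    for i in np.flatnonzero(arr.sum(axis=1) == 0):
        arr[i, rng.integers(n_taxa)] = 1.0
    df = pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(n_sites)],
        columns=[f"t{j:03d}" for j in range(n_taxa)],
    )
    return CompositionMatrix.from_dataframe(df)


@pytest.fixture(scope="session")
def small_world():
    cfg = WorldConfig(n_sites=40, n_species=120, n_genera=12)
    return generate_world(cfg, seed=7)
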