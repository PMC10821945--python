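import numpy as np
import pytest

import trajdiff as td


@pytest.fixture(scope="session")
def y_dataset():
    """Small neutral two-condition dataset on the branching topology."""
    ds, truth = td.simulate_dataset(
        td.SimSpec(n_per_condition=400, n_genes=30, seed=11)
    )
    return ds, truth


@pytest.fixture(scope="session")
def y_fit(y_dataset):
    ds, _ = y_dataset
    skel = td.fit_skeleton(ds, root="O-M:0")
    return td.project_cells(ds, skel)


@pytest.fixture(scope="session")
def linear_dataset():
    """Small neutral dataset on a single-lineage topology."""
    ds, truth = td.simulate_dataset(
        td.SimSpec(topology="linear", n_per_condition=300, n_genes=20, seed=13)
    )
    return ds, truth


def make_toy_dataset(embedding, clusters, conditions=None, counts=None):
    """Hand-built CellDataset around an explicit embedding."""
    n = embedding.shape[0]
    if conditions is None:
        conditions = np.array(["c1"] * n)
    if counts is None:
        counts = np.ones((3, n), dtype=int)
    return td.CellDataset(
        counts=counts,
        cell_ids=[f"cell_{i}" for i in range(n)],
        conditions=np.asarray(conditions),
        clusters=np.asarray(clusters),
        embedding=np.asarray(embedding, dtype=float),
    )
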