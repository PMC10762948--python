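"""Shared fixtures: small simulated datasets reused across the suite.

All fixtures are generated programmatically; scales are kept small so
individual method fits take well under a second.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dabench.bench import plant_and_assign, prepare_base
from dabench.datasets import MultiSampleDataset


@pytest.fixture(scope="session")
def cluster_base():
    """Three discrete populations (M2 twice the size of M1/M3), 900 cells."""
    return prepare_base("cluster", seed=7, n_cells=900, n_genes=100, k=40)


@pytest.fixture(scope="session")
def linear_base():
    """Small linear-trajectory dataset (5 latent-time segments)."""
    return prepare_base("linear", seed=7, n_cells=1200, n_genes=120, k=40)


@pytest.fixture(scope="session")
def cluster_case(cluster_base):
    """Planted DA on M1 at ratio 0.95 with assigned conditions."""
    ds, truth, graph = plant_and_assign(cluster_base, "M1", 0.95, seed=3, k=40)
    return ds, truth, graph


@pytest.fixture()
def two_blob_dataset():
    """Two well-separated blobs; blob B holds only condition-C2 cells.

    Hand-assigned metadata (not drawn from the planting model) so edge
    cases like disconnected graph components can be tested exactly.
    """
    rng = np.random.default_rng(0)
    n_half = 40
    coords = np.vstack(
        [rng.normal(0.0, 0.5, (n_half, 5)), rng.normal(50.0, 0.5, (n_half, 5))]
    )
    counts = rng.poisson(5.0, (2 * n_half, 10))
    cond = np.array(["C1", "C2"] * (n_half // 2) + ["C2"] * n_half)
    rep = np.tile(["R1", "R2"], n_half)
    meta = pd.DataFrame(
        {
            "population": ["A"] * n_half + ["B"] * n_half,
            "condition": cond,
            "replicate": rep,
            "sample": [f"{c}_{r}" for c, r in zip(cond, rep)],
        },
        index=pd.Index([f"cell{i}" for i in range(2 * n_half)], name="cell_id"),
    )
    return MultiSampleDataset(
        counts=counts, cell_meta=meta, embeddings={"pca": coords}
    )
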