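"""Neighbourhood-based DA testing on the kNN graph.

Index cells are sampled at a small fraction; each index cell's
first-order graph neighbourhood (itself included) is a testing unit.
Per-sample neighbourhood counts are tested with the NB-GLM and the
spatial FDR (weights = reciprocal of the distance to the k-th
neighbour, a local density proxy).  Because neighbourhoods overlap, a
cell's score is the signed average of its neighbourhoods' DA scores.
"""

from __future__ import annotations

import numpy as np

from ._glm import nb_glm_test, spatial_fdr
from .base import DAMethod, DAResult, count_units


class Milo(DAMethod):
    name = "milo"

    def __init__(
        self,
        dataset,
        graph=None,
        embedding="pca",
        use_batch=False,
        sample_fraction: float = 0.1,
        alpha: float = 0.1,
        seed: int = 0,
    ):
        super().__init__(dataset, graph, embedding, use_batch)
        if not 0 < sample_fraction <= 1:
            raise ValueError("sample_fraction must lie in (0, 1]")
        self.sample_fraction = sample_fraction
        self.alpha = alpha
        self.seed = seed

    def fit(self) -> DAResult:
        graph = self._require_graph()
        n = graph.n_cells
        n_index = int(self.sample_fraction * n)
        if n_index == 0:
            raise ValueError("sample_fraction yields zero index cells")
        rng = np.random.default_rng(self.seed)
        index_cells = np.sort(rng.choice(n, size=n_index, replace=False))

        memberships = [
            np.union1d(graph.neighbors_of(i), [i]) for i in index_cells
        ]
        # density proxy: reciprocal distance to the k-th nearest neighbour
        kth = graph.knn_distances[index_cells, -1]
        weights = 1.0 / np.maximum(kth, 1e-12)

        design = self.design
        counts = count_units(memberships, design.codes, design.n_groups)
        table = nb_glm_test(counts, design.condition, design.batch)
        significant, adjusted = spatial_fdr(
            table["p_value"].to_numpy(), weights, self.alpha
        )
        table["spatial_fdr"] = adjusted
        table["significant"] = significant
        table["density_weight"] = weights
        table.insert(0, "index_cell", index_cells)

        signed = np.zeros(n)
        coverage = np.zeros(n)
        assessed = np.zeros(n, dtype=bool)
        cell_sig = np.zeros(n, dtype=bool)
        unit_score = np.sign(table["logFC"].to_numpy()) * (1.0 - adjusted)
        for u, members in enumerate(memberships):
            assessed[members] = True
            signed[members] += unit_score[u]
            coverage[members] += 1.0
            if significant[u]:
                cell_sig[members] = True
        # average rather than raw sum: a cell covered by many neutral
        # neighbourhoods must not outscore one covered by a single
        # strongly DA neighbourhood
        signed = signed / np.maximum(coverage, 1.0)

        return DAResult(
            method=self.name,
            cell_table=self._cell_frame(
                np.abs(signed), np.sign(signed), cell_sig, ~assessed
            ),
            unit_table=table,
            hyperparams={
                "sample_fraction": self.sample_fraction,
                "k": graph.k,
                "alpha": self.alpha,
                "use_batch": self.use_batch,
                "seed": self.seed,
            },
        )


def run_milo(dataset, graph=None, **params) -> DAResult:
    return Milo(dataset, graph, **params).fit()
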