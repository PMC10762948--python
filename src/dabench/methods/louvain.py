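"""Cluster-level DA testing via Louvain modularity clustering.

Cells are partitioned with the Louvain algorithm on the weighted kNN
graph; per-cluster per-sample counts go through the same NB-GLM as the
neighbourhood methods.  Clusters partition the cells (no overlap), so
multiple testing uses plain Benjamini-Hochberg and every cell inherits
its cluster's score and direction.
"""

from __future__ import annotations

import random

import igraph as ig
import numpy as np
from statsmodels.stats.multitest import multipletests

from ._glm import nb_glm_test
from .base import DAMethod, DAResult, count_units


class Louvain(DAMethod):
    name = "louvain"

    def __init__(
        self,
        dataset,
        graph=None,
        embedding="pca",
        use_batch=False,
        resolution: float = 1.0,
        alpha: float = 0.1,
        seed: int = 0,
    ):
        super().__init__(dataset, graph, embedding, use_batch)
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.resolution = resolution
        self.alpha = alpha
        self.seed = seed

    def _cluster(self) -> np.ndarray:
        adj = self._require_graph().adjacency.tocoo()
        mask = adj.row < adj.col
        edges = list(zip(adj.row[mask], adj.col[mask]))
        weights = adj.data[mask].tolist()
        g = ig.Graph(n=adj.shape[0], edges=edges)
        state = random.Random(self.seed)
        old = ig.set_random_number_generator(state)
        try:
            part = g.community_multilevel(weights=weights, resolution=self.resolution)
        finally:
            ig.set_random_number_generator(old if old is not None else random)
        return np.asarray(part.membership)

    def fit(self) -> DAResult:
        membership = self._cluster()
        clusters = np.unique(membership)
        member_lists = [np.flatnonzero(membership == c) for c in clusters]

        design = self.design
        counts = count_units(member_lists, design.codes, design.n_groups)
        table = nb_glm_test(counts, design.condition, design.batch)
        _, adjusted, *_ = multipletests(
            table["p_value"].to_numpy(), method="fdr_bh"
        )
        table["fdr"] = adjusted
        table["significant"] = adjusted <= self.alpha
        table.insert(0, "cluster", clusters)
        table["n_cells"] = [len(m) for m in member_lists]

        cluster_score = 1.0 - adjusted
        cluster_sign = np.sign(table["logFC"].to_numpy())
        score = cluster_score[membership]
        direction = cluster_sign[membership]
        cell_sig = table["significant"].to_numpy()[membership]

        return DAResult(
            method=self.name,
            cell_table=self._cell_frame(score, direction, cell_sig),
            unit_table=table,
            hyperparams={
                "resolution": self.resolution,
                "alpha": self.alpha,
                "use_batch": self.use_batch,
                "seed": self.seed,
            },
        )


def run_louvain(dataset, graph=None, **params) -> DAResult:
    return Louvain(dataset, graph, **params).fit()
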