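"""Hypersphere-based DA testing (mass-cytometry style).

Random cells become hypersphere centers; cells within a fixed radius of
a center form the testing unit.  Per-sample counts in each hypersphere
go through the NB-GLM, and discoveries are controlled by the spatial
FDR with weights equal to the reciprocal of the local center density.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._glm import nb_glm_test, spatial_fdr
from .base import DAMethod, DAResult, count_units


class Cydar(DAMethod):
    name = "cydar"

    def __init__(
        self,
        dataset,
        graph=None,
        embedding="pca",
        use_batch=False,
        radius: float | None = None,
        center_fraction: float = 0.1,
        alpha: float = 0.1,
        seed: int = 0,
    ):
        super().__init__(dataset, graph, embedding, use_batch)
        if radius is not None and radius <= 0:
            raise ValueError("radius must be positive")
        if not 0 < center_fraction <= 1:
            raise ValueError("center_fraction must lie in (0, 1]")
        self.radius = radius
        self.center_fraction = center_fraction
        self.alpha = alpha
        self.seed = seed

    def _default_radius(self, coords: np.ndarray) -> float:
        # 1.5x the median distance to the k-th neighbour: hyperspheres a
        # bit wider than a kNN ball, but still inside one population
        if self.graph is not None:
            return 1.5 * float(np.median(self.graph.knn_distances[:, -1]))
        k = min(30, coords.shape[0] - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        dist, _ = nn.kneighbors(coords)
        return 1.5 * float(np.median(dist[:, -1]))

    def fit(self) -> DAResult:
        coords = self._coords()
        n = coords.shape[0]
        radius = self.radius if self.radius is not None else self._default_radius(coords)
        rng = np.random.default_rng(self.seed)
        n_centers = max(1, int(round(self.center_fraction * n)))
        centers = np.sort(rng.choice(n, size=n_centers, replace=False))

        tree = NearestNeighbors(radius=radius).fit(coords)
        memberships = tree.radius_neighbors(coords[centers], return_distance=False)
        memberships = [np.sort(m) for m in memberships]

        # density weight: reciprocal of #centers within the radius
        center_tree = NearestNeighbors(radius=radius).fit(coords[centers])
        near = center_tree.radius_neighbors(coords[centers], return_distance=False)
        density = np.array([len(m) for m in near], dtype=float)
        weights = 1.0 / np.maximum(density, 1.0)

        design = self.design
        counts = count_units(memberships, design.codes, design.n_groups)
        table = nb_glm_test(counts, design.condition, design.batch)
        significant, adjusted = spatial_fdr(
            table["p_value"].to_numpy(), weights, self.alpha
        )
        table["spatial_fdr"] = adjusted
        table["significant"] = significant
        table["density_weight"] = weights
        table.insert(0, "center_cell", centers)

        signed = np.zeros(n)
        coverage = np.zeros(n)
        cell_sig = np.zeros(n, dtype=bool)
        assessed = np.zeros(n, dtype=bool)
        # rank hyperspheres by adjusted value; raw p breaks the ties that
        # appear when every adjusted value saturates at 1
        unit_score = (1.0 - adjusted) + 1e-3 * (1.0 - table["p_value"].to_numpy())
        unit_sign = np.sign(table["logFC"].to_numpy())
        for u, members in enumerate(memberships):
            assessed[members] = True
            signed[members] += unit_sign[u] * unit_score[u]
            coverage[members] += 1.0
            if significant[u]:
                cell_sig[members] = True
        # signed average over the overlapping hyperspheres containing a
        # cell: opposite-direction evidence cancels instead of competing
        signed = signed / np.maximum(coverage, 1.0)
        score = np.abs(signed)
        direction = np.sign(signed)
        score[~assessed] = 0.0

        return DAResult(
            method=self.name,
            cell_table=self._cell_frame(score, direction, cell_sig, ~assessed),
            unit_table=table,
            hyperparams={
                "radius": radius,
                "center_fraction": self.center_fraction,
                "alpha": self.alpha,
                "use_batch": self.use_batch,
                "seed": self.seed,
            },
        )


def run_cydar(dataset, graph=None, **params) -> DAResult:
    return Cydar(dataset, graph, **params).fit()
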