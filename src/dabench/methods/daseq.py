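"""Multiscale logistic-regression DA scoring.

Each cell gets a feature vector of condition-imbalance fractions
(n_C2 - n_C1) / k among its k nearest neighbours for several k; a
ridge-regularized logistic regression predicting the cell's own
condition smooths these into a per-cell DA measure 2*p - 1 in [-1, 1].
Permuting condition labels yields the null extremes used as
significance cut-offs.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors

from .base import DAMethod, DAResult


def _default_k_list(n_cells: int) -> list[int]:
    ks = [k for k in range(50, 501, 50) if k < n_cells]
    return ks or [max(2, n_cells // 2)]


class DASeq(DAMethod):
    name = "daseq"

    def __init__(
        self,
        dataset,
        graph=None,
        embedding="pca",
        use_batch=False,
        k_list: list[int] | None = None,
        ridge: float = 1e-3,
        n_permutations: int = 50,
        seed: int = 0,
    ):
        super().__init__(dataset, graph, embedding, use_batch)
        n = dataset.n_cells
        if k_list is None:
            k_list = _default_k_list(n)
        k_list = list(k_list)
        if any(b <= a for a, b in zip(k_list, k_list[1:])):
            raise ValueError("k_list must be strictly increasing")
        if k_list[-1] >= n:
            raise ValueError("max(k_list) must be below the number of cells")
        self.k_list = k_list
        self.ridge = ridge
        self.n_permutations = n_permutations
        self.seed = seed

    def _features(self, z: np.ndarray, nbr_idx: np.ndarray) -> np.ndarray:
        """Centered imbalance fraction mean(z) over the first k neighbours."""
        cums = np.cumsum(z[nbr_idx], axis=1)
        cols = [cums[:, k - 1] / k for k in self.k_list]
        return np.column_stack(cols)

    def fit(self) -> DAResult:
        coords = self._coords()
        n = coords.shape[0]
        cond = (self.dataset.cell_meta["condition"] == "C2").to_numpy()
        kmax = self.k_list[-1]
        nn = NearestNeighbors(n_neighbors=kmax + 1).fit(coords)
        _, idx = nn.kneighbors(coords)
        idx = idx[:, 1:]

        z = np.where(cond, 1.0, -1.0)
        clf = LogisticRegression(C=1.0 / self.ridge, max_iter=1000)

        def measures(zvec, yvec):
            X = self._features(zvec, idx)
            fitted = clf.fit(X, yvec)
            return 2.0 * fitted.predict_proba(X)[:, list(fitted.classes_).index(True)] - 1.0

        measure = measures(z, cond)

        rng = np.random.default_rng(self.seed)
        lo, hi = np.inf, -np.inf
        for _ in range(self.n_permutations):
            perm = rng.permutation(n)
            m = measures(z[perm], cond[perm])
            lo = min(lo, m.min())
            hi = max(hi, m.max())

        significant = (measure > hi) | (measure < lo)
        return DAResult(
            method=self.name,
            cell_table=self._cell_frame(
                np.abs(measure), np.sign(measure), significant
            ),
            unit_table=self._unit_table(measure, lo, hi),
            hyperparams={
                "k_list": self.k_list,
                "ridge": self.ridge,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
            },
        )

    @staticmethod
    def _unit_table(measure, lo, hi):
        import pandas as pd

        return pd.DataFrame(
            {
                "unit": ["all_cells"],
                "null_lower": [lo],
                "null_upper": [hi],
                "n_beyond_null": [int(np.sum((measure > hi) | (measure < lo)))],
            }
        )


def run_daseq(dataset, graph=None, **params) -> DAResult:
    return DASeq(dataset, graph, **params).fit()
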