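"""Co-varying neighbourhood analysis via a random-walk abundance matrix.

A column-stochastic Markov matrix with self-loops propagates each
sample's cells over the kNN graph for ``s`` steps; row-normalizing the
resulting arrival-mass matrix gives the neighbourhood abundance matrix
(NAM), whose rows describe where each sample's cells concentrate.  The
sample-level condition covariate is regressed on the NAM's top left
singular vectors, choosing the component count by a multivariate
F-test; projecting the winning coefficients back through the right
singular vectors yields a per-cell "smoothed correlation" gamma whose
null distribution comes from permuting the covariate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse, stats

from ..datasets import MultiSampleDataset
from ..preprocess import CellGraph
from .base import DAMethod, DAResult, GroupDesign, group_design


class NamModel:
    """Random-walk Markov matrix, arrival masses and row-stochastic NAM."""

    def __init__(
        self,
        markov: sparse.csr_matrix,
        steps: int,
        arrivals: np.ndarray,
        nam: np.ndarray,
        design: GroupDesign,
    ):
        self.markov = markov
        self.steps = steps
        self.arrivals = arrivals
        self.nam = nam
        self.design = design
        # filled by the association test
        self.svd: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self.coefficients: np.ndarray | None = None
        self.selected_k: int | None = None
        self.gamma: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.nam.shape[1]


def build_nam(
    dataset: MultiSampleDataset,
    graph: CellGraph,
    steps: int = 3,
    use_batch: bool = False,
) -> NamModel:
    """Construct the samples x cells neighbourhood abundance matrix.

    The Markov matrix normalizes each column of (I + A) by one plus the
    column sum of A, so isolated nodes keep a self-loop and no division
    by zero can occur; columns sum to 1 by construction and NAM rows are
    normalized to sum to 1.
    """
    if steps < 0:
        raise ValueError("steps must be non-negative")
    design = group_design(dataset, use_batch=use_batch)
    A = graph.adjacency.tocsc()
    n = A.shape[0]
    colsum = np.asarray(A.sum(axis=0)).ravel()
    scale = 1.0 / (1.0 + colsum)
    markov = ((sparse.identity(n, format="csc") + A) @ sparse.diags(scale)).tocsr()

    # R = S @ markov^steps, computed as repeated transposed products
    S = np.zeros((design.n_groups, n))
    S[design.codes, np.arange(n)] = 1.0
    Rt = S.T.copy()
    Mt = markov.T.tocsr()
    for _ in range(steps):
        Rt = Mt @ Rt
    R = Rt.T
    nam = R / R.sum(axis=1, keepdims=True)
    assert np.allclose(np.asarray(markov.sum(axis=0)).ravel(), 1.0), "walk matrix not column-stochastic"
    assert np.allclose(nam.sum(axis=1), 1.0), "NAM rows must sum to 1"
    return NamModel(markov=markov, steps=steps, arrivals=R, nam=nam, design=design)


def _residualize(M: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Project out covariate columns (with intercept) from M's columns."""
    X = np.column_stack([np.ones(M.shape[0]), covariates])
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta


def _association(Qc: np.ndarray, y: np.ndarray, max_k: int):
    """Best-k regression of y on left singular vectors; returns gamma."""
    U, D, Vt = np.linalg.svd(Qc, full_matrices=False)
    N = len(y)
    tss = float(y @ y)
    best = None
    for k in range(1, max_k + 1):
        beta = U[:, :k].T @ y
        rss = max(tss - float(beta @ beta), 1e-300)
        dof = N - k - 1
        if dof <= 0:
            break
        r2 = 1.0 - rss / tss
        f = (r2 / k) / ((1.0 - r2) / dof)
        p = float(stats.f.sf(f, k, dof))
        if best is None or p < best[0]:
            best = (p, k, beta)
    if best is None:
        raise ValueError("no usable component count (k grid empty)")
    p, k, beta = best
    gamma = Vt[:k].T @ (D[:k] * beta)
    return gamma, k, beta, p, (U, D, Vt)


class Cna(DAMethod):
    name = "cna"

    def __init__(
        self,
        dataset,
        graph=None,
        embedding="pca",
        use_batch=False,
        steps: int = 3,
        max_k: int | None = None,
        n_permutations: int = 1000,
        fdr: float = 0.05,
        seed: int = 0,
    ):
        super().__init__(dataset, graph, embedding, use_batch)
        if self.design.n_groups < 4:
            raise ValueError("CNA needs at least 4 samples")
        self.steps = steps
        self.max_k = max_k
        self.n_permutations = n_permutations
        self.fdr = fdr
        self.seed = seed

    def fit(self) -> DAResult:
        graph = self._require_graph()
        nam = build_nam(self.dataset, graph, self.steps, self.use_batch)
        design = nam.design
        N = design.n_groups
        max_k = self.max_k if self.max_k is not None else min(10, N - 2)
        if max_k < 1:
            raise ValueError("too few samples for any component")

        y = design.condition.astype(float)
        if y.min() == y.max():
            raise ValueError("constant covariate")
        Q = nam.nam
        Qc = Q - Q.mean(axis=0)
        yc = y - y.mean()
        if self.use_batch and design.batch is not None:
            levels = sorted(set(design.batch))
            B = np.column_stack(
                [(np.asarray(design.batch) == lev).astype(float) for lev in levels[1:]]
            )
            Qc = _residualize(Qc, B)
            yc = _residualize(yc[:, None], B).ravel()

        gamma, k_star, beta, p_global, svd = _association(Qc, yc, max_k)
        nam.svd = svd
        nam.coefficients = beta
        nam.selected_k = k_star
        nam.gamma = gamma

        rng = np.random.default_rng(self.seed)
        null_abs = []
        for _ in range(self.n_permutations):
            yp = rng.permutation(yc)
            g, *_ = _association(Qc, yp, max_k)
            null_abs.append(np.abs(g))
        null_abs = np.sort(np.concatenate(null_abs))

        # empirical per-cell FDR: compare |gamma| against the pooled null
        obs = np.abs(gamma)
        order = np.argsort(-obs, kind="stable")
        n_cells = len(obs)
        n_null = len(null_abs)
        exceed = n_null - np.searchsorted(null_abs, obs[order], side="left")
        expected_false = exceed / max(self.n_permutations, 1)
        fdp = expected_false / np.arange(1, n_cells + 1)
        qs = np.minimum(np.minimum.accumulate(fdp[::-1])[::-1], 1.0)
        qvals = np.empty(n_cells)
        qvals[order] = qs

        unit_table = pd.DataFrame(
            {
                "component_count": [k_star],
                "p_value": [p_global],
                "n_significant_cells": [int((qvals <= self.fdr).sum())],
            }
        )
        result = DAResult(
            method=self.name,
            cell_table=self._cell_frame(obs, np.sign(gamma), qvals <= self.fdr),
            unit_table=unit_table,
            hyperparams={
                "steps": self.steps,
                "max_k": max_k,
                "n_permutations": self.n_permutations,
                "fdr": self.fdr,
                "use_batch": self.use_batch,
                "seed": self.seed,
            },
        )
        result.cell_table["gamma"] = gamma
        result.cell_table["fdr"] = qvals
        result.nam = nam
        return result


def cna_test(nam: NamModel, y: np.ndarray, max_k: int, n_permutations: int, fdr: float, seed: int):
    """Functional form of the NAM association test (see :class:`Cna`)."""
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("constant covariate")
    Qc = nam.nam - nam.nam.mean(axis=0)
    yc = y - y.mean()
    gamma, k_star, beta, p_global, svd = _association(Qc, yc, max_k)
    nam.svd, nam.coefficients, nam.selected_k, nam.gamma = svd, beta, k_star, gamma
    rng = np.random.default_rng(seed)
    null = [
        np.abs(_association(Qc, rng.permutation(yc), max_k)[0])
        for _ in range(n_permutations)
    ]
    return gamma, k_star, p_global, np.concatenate(null) if null else np.array([])


def run_cna(dataset, graph=None, **params) -> DAResult:
    return Cna(dataset, graph, **params).fit()
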