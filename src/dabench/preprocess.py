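"""Normalization, PCA embedding and kNN graph construction.

These steps are shared by all DA testing methods: scRNA-seq counts get a
log(x+1) transform, CyTOF-style intensities an arcsinh with cofactor 5,
cells are embedded into their top principal components (50 by default),
and a weighted k-nearest-neighbour graph over cells is the common
substrate for the clustering-free methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .datasets import MultiSampleDataset


def log1p_normalize(counts: np.ndarray) -> np.ndarray:
    """Elementwise natural log of (count + 1)."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return np.log1p(counts)


def arcsinh_transform(x: np.ndarray, cofactor: float = 5.0) -> np.ndarray:
    """Elementwise asinh(x / cofactor); the CyTOF-standard transform."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(x) / cofactor)


@dataclass
class Embedding:
    """Centered PCA embedding with loadings and explained variance."""

    coords: np.ndarray            # cells x d
    mean: np.ndarray              # per-gene centering vector
    components: np.ndarray        # d x genes, orthonormal rows
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def pca_embed(normalized: np.ndarray, n_components: int = 50) -> Embedding:
    """Exact (full-SVD) PCA with a deterministic sign convention.

    Each component is flipped so that its largest-magnitude loading is
    positive; requesting more components than the matrix rank truncates
    with a warning.
    """
    x = np.asarray(normalized, dtype=float)
    n, p = x.shape
    max_rank = min(n, p)
    if n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components but rank is at most "
            f"{max_rank}; truncating"
        )
        n_components = max_rank
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # sign convention: largest-|.| loading entry of each component positive
    flip = np.sign(vt[np.arange(n_components), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    coords = u * s
    explained = (s**2) / max(n - 1, 1)
    return Embedding(coords=coords, mean=mean, components=vt, explained_variance=explained)


def embed_dataset(
    dataset: MultiSampleDataset,
    n_components: int = 50,
    transform: str = "log1p",
    name: str = "pca",
) -> MultiSampleDataset:
    """Normalize counts and attach a PC embedding to the dataset."""
    if transform == "log1p":
        normalized = log1p_normalize(dataset.counts)
    elif transform == "arcsinh":
        normalized = arcsinh_transform(dataset.counts)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    emb = pca_embed(normalized, n_components=n_components)
    out = dataset.copy()
    out.embeddings[name] = emb.coords
    return out


KERNELS = ("binary", "gaussian", "alpha_decay")


@dataclass
class CellGraph:
    """Symmetric weighted kNN graph over cells.

    ``adjacency`` has zero diagonal and non-negative weights; the raw
    directed kNN indices/distances are kept because several methods
    (Milo's neighbourhoods and density weights, DA-seq's multiscale
    features, Cydar's default radius) reuse them.
    """

    adjacency: sparse.csr_matrix
    k: int
    kernel: str
    knn_indices: np.ndarray    # cells x k (self excluded)
    knn_distances: np.ndarray  # cells x k

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def neighbors_of(self, i: int) -> np.ndarray:
        """First-order neighbours in the symmetrized graph (self excluded)."""
        return self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]

    def save_edgelist(self, path) -> None:
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i}\t{j}\t{w:.8g}\n")


def build_knn_graph(
    embedding: np.ndarray,
    k: int = 30,
    kernel: str = "binary",
    alpha: float = 10.0,
) -> CellGraph:
    """Directed Euclidean kNN, symmetrized by union (elementwise max).

    Kernels: ``binary`` (weight 1), ``gaussian`` (bandwidth = global
    median kNN distance), ``alpha_decay`` (adaptive bandwidth = distance
    to the ceil(k/3)-th neighbour, exponent ``alpha``).  kNN ties are
    broken by cell index.
    """
    coords = np.asarray(embedding, dtype=float)
    n = coords.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # drop self (always first at distance 0); remaining order is by
    # distance with index order as tie-break
    dist, idx = dist[:, 1:], idx[:, 1:]

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    if kernel == "binary":
        data = np.ones(n * k)
    elif kernel == "gaussian":
        bw = np.median(dist)
        data = np.exp(-(dist.ravel() ** 2) / max(bw, 1e-12) ** 2)
    else:  # alpha_decay
        j = max(int(np.ceil(k / 3)) - 1, 0)
        local_bw = np.maximum(dist[:, j], 1e-12)
        scaled = dist / local_bw[:, None]
        data = np.exp(-(scaled.ravel() ** alpha))

    directed = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    adjacency = directed.maximum(directed.T)
    adjacency.setdiag(0)
    adjacency.eliminate_zeros()
    return CellGraph(
        adjacency=adjacency.tocsr(),
        k=k,
        kernel=kernel,
        knn_indices=idx,
        knn_distances=dist,
    )
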