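"""Synthetic multi-sample single-cell data with planted DA effects.

The generator emulates the three benchmark topologies — a linear
trajectory, a bifurcating (branch) trajectory and discrete clusters —
as latent structures whose per-gene means feed a negative-binomial
observation model.  Differential abundance between two conditions (C1,
C2) is planted by giving each cell a probability of originating from C2
that increases with its similarity to the centroid of a chosen target
population:

    P(C2)_i = (w_i - min w) / (max w - min w) * (p_DA - 0.5) + 0.5

where ``w_i`` is the logit-transformed similarity (a sharply decaying
kernel of the variance-weighted distance) between cell ``i`` and the
target centroid in PC space, and ``p_DA`` (the DA ratio) is the
maximal enrichment of C2.  Cells are then labelled NegLFC /
PosLFC / NotDA by a symmetric threshold ``t`` derived from the target
population's share of the dataset.

Batch effects are a per-batch Gaussian shift applied to every cell's PC
profile, mimicking a technical offset that is orthogonal to condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit, softplus

from .datasets import GroundTruth, MultiSampleDataset

logger = logging.getLogger(__name__)

TOPOLOGIES = ("linear", "branch", "cluster")

# stable per-purpose RNG stream codes so experiments can vary one
# factor (e.g. the condition assignment) while holding others fixed
_STREAMS = {"topology": 11, "planting": 13, "conditions": 17, "batch": 19, "subsample": 23}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class TopologyConfig:
    """Latent-structure configuration for one synthetic dataset.

    ``populations`` maps population name to cell count; when omitted the
    topology-specific defaults below are used.  ``dispersion`` is the
    common NB dispersion (variance = mu + dispersion * mu^2).
    """

    kind: str
    n_cells: int = 7500
    n_genes: int = 500
    populations: dict[str, int] | None = None
    dispersion: float = 0.3
    expression_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TOPOLOGIES:
            raise ValueError(f"unknown topology kind {self.kind!r}")
        if self.n_cells < 2:
            raise ValueError("n_cells must be at least 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be at least 1")
        if self.populations is not None:
            sizes = list(self.populations.values())
            if any(s <= 0 for s in sizes):
                raise ValueError("every population must be non-empty")
            if sum(sizes) != self.n_cells:
                raise ValueError("population sizes must sum to n_cells")


@dataclass
class BatchConfig:
    """Gaussian batch-shift configuration (``batch_sd`` = batchSd)."""

    batch_sd: float
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be non-negative")
        if self.n_batches < 1:
            raise ValueError("n_batches must be at least 1")


def default_config(kind: str, seed: int = 0) -> TopologyConfig:
    """Shipped benchmark configurations for the three topologies."""
    if kind == "cluster":
        # unbalanced on purpose: M2 holds ~50% of cells
        return TopologyConfig(
            kind="cluster",
            n_cells=2700,
            n_genes=500,
            populations={"M1": 675, "M2": 1350, "M3": 675},
            seed=seed,
        )
    return TopologyConfig(kind=kind, n_cells=7500, n_genes=500, seed=seed)


# ---------------------------------------------------------------------------
# topology simulation
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _linear_latent(rng, n_cells):
    u = np.sort(rng.uniform(0.0, 1.0, n_cells))
    # 5 contiguous latent-time segments, each usable as a planting target
    seg = np.minimum((u * 5).astype(int), 4)
    pop = np.array([f"L{i + 1}" for i in seg])
    return u, None, pop


def _branch_latent(rng, n_cells):
    u = rng.uniform(0.0, 1.0, n_cells)
    arm = rng.integers(0, 2, n_cells)  # branch choice beyond the root
    pop = np.empty(n_cells, dtype=object)
    trunk = u <= 0.4
    pop[trunk & (u <= 0.2)] = "T1"
    pop[trunk & (u > 0.2)] = "T2"
    for a, name in ((0, "A"), (1, "B")):
        on = (~trunk) & (arm == a)
        pop[on & (u <= 0.7)] = f"{name}1"
        pop[on & (u > 0.7)] = f"{name}2"
    return u, arm, pop


def simulate_topology(config: TopologyConfig) -> MultiSampleDataset:
    """Draw a count matrix with the requested latent topology.

    Counts are NB-distributed around per-gene means that are smooth in
    latent time (linear/branch) or constant per population (cluster).
    Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed, "topology")
    n, p = config.n_cells, config.n_genes

    if config.kind == "cluster":
        pops = config.populations or default_config("cluster").populations
        if sum(pops.values()) != n:
            raise ValueError("population sizes must sum to n_cells")
        names = list(pops)
        base = rng.normal(0.0, 0.5, p)
        offsets = {m: rng.normal(0.0, 0.7, p) for m in names}
        pop = np.concatenate([[m] * pops[m] for m in names])
        log_mu = np.stack([base + offsets[m] for m in pop])
        mean = config.expression_scale * np.exp(log_mu)
        latent = np.full(n, np.nan)
    else:
        if config.kind == "linear":
            latent, arm, pop = _linear_latent(rng, n)
        else:
            latent, arm, pop = _branch_latent(rng, n)
        # gene programs: an affine trend plus a periodic wave with random
        # phase, so the trajectory curves through expression space (waves
        # of gene activation) instead of collapsing onto a single axis
        a = rng.normal(0.5, 1.0, p)
        b = rng.normal(0.0, 3.0, p)
        c = rng.normal(0.0, 1.2, p)
        freq = rng.integers(1, 4, p)
        phase = rng.uniform(0.0, 2.0 * np.pi, p)
        u = latent[:, None]
        eta = (
            a[None, :]
            + b[None, :] * u
            + c[None, :] * np.sin(np.pi * freq[None, :] * u + phase[None, :])
        )
        if config.kind == "branch":
            # per-arm programs that vanish at the branch point (u = 0.4)
            excess = np.maximum(latent - 0.4, 0.0)[:, None] / 0.6
            for arm_id in (0, 1):
                d = rng.normal(0.0, 3.0, p)
                g = rng.normal(0.0, 2.0, p)
                hfreq = rng.integers(1, 4, p)
                psi = rng.uniform(0.0, 2.0 * np.pi, p)
                wave = np.sin(np.pi * hfreq[None, :] * excess + psi[None, :]) - np.sin(
                    psi[None, :]
                )
                on = (arm == arm_id)[:, None]
                eta = eta + on * (d[None, :] * excess + g[None, :] * wave)
        mean = config.expression_scale * softplus(eta)

    counts = _nb_sample(rng, mean, config.dispersion)
    meta = pd.DataFrame(
        {"population": pop},
        index=pd.Index([f"cell{i}" for i in range(n)], name="cell_id"),
    )
    if config.kind != "cluster":
        meta["latent_time"] = latent
    return MultiSampleDataset(counts=counts, cell_meta=meta)


# ---------------------------------------------------------------------------
# DA planting
# ---------------------------------------------------------------------------

def plant_da(
    dataset: MultiSampleDataset,
    target_population: str,
    p_da: float,
    seed: int = 0,
    embedding: str = "pca",
) -> GroundTruth:
    """Assign every cell a probability of being generated under C2.

    ``w`` is the logit of a compact similarity exp(-(d / sigma)^6 / 2)
    to the target-population centroid, where ``d`` is a weighted
    Euclidean distance in PC space with each component weighted by its
    variance (so noise-dominated trailing components contribute little)
    and ``sigma`` is the median weighted centroid distance over the
    *target* cells.  Only the ranks of ``w`` matter for the min-max
    rescaling onto [0.5, p_da]; the target-scale bandwidth and fast
    decay keep the background near the similarity floor (P(C2) close to
    0.5) while the planted effect decays smoothly inside and just
    around the target population, so the overall C2 excess stays
    proportional to the target's share of cells.
    """
    if not 0.0 < p_da < 1.0:
        raise ValueError("p_da must lie strictly between 0 and 1")
    if embedding not in dataset.embeddings:
        raise ValueError(f"dataset has no {embedding!r} embedding")
    in_target = dataset.cell_meta["population"] == target_population
    if not in_target.any():
        raise ValueError(f"unknown or empty population {target_population!r}")

    coords = np.asarray(dataset.embeddings[embedding], dtype=float)
    centroid = coords[in_target.to_numpy()].mean(axis=0)
    weights = coords.var(axis=0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate geometry: all cells coincide with the centroid")
    weights = weights / total
    d = np.sqrt(((coords - centroid) ** 2 * weights).sum(axis=1))
    sigma = np.median(d[in_target.to_numpy()])
    if sigma <= 0:
        raise ValueError("degenerate geometry: all cells coincide with the centroid")
    s = np.exp(-((d / sigma) ** 6) / 2.0)
    w = logit(np.clip(s, 1e-6, 1.0 - 1e-6))

    wmin, wmax = w.min(), w.max()
    if wmax == wmin:
        raise ValueError("degenerate similarity: max(w) equals min(w)")
    prob = (w - wmin) / (wmax - wmin) * (p_da - 0.5) + 0.5

    ids = dataset.cell_ids
    return GroundTruth(
        p_da=float(p_da),
        prob_c2=pd.Series(prob, index=ids, name="prob_c2"),
        w=pd.Series(w, index=ids, name="w"),
        target_population=target_population,
    )


def ground_truth_labels(
    truth: GroundTruth,
    target_proportion: float,
    t_bounds: tuple[float, float] = (0.05, 0.45),
) -> GroundTruth:
    """Derive the label threshold ``t`` and assign three-way labels.

    ``t`` is chosen so that the labelled tail holds approximately the
    target population's share of cells: for an enrichment (p_da > 0.5)
    ``t = 1 - q`` with ``q`` the (1 - proportion)-quantile of prob_c2;
    for a depletion the mirror-image quantile is used.  ``t`` is clipped
    into ``t_bounds`` and always stays below 0.5.
    """
    if not 0.0 < target_proportion < 1.0:
        raise ValueError("target_proportion must lie in (0, 1)")
    prob = truth.prob_c2.to_numpy()
    if truth.p_da >= 0.5:
        t = 1.0 - float(np.quantile(prob, 1.0 - target_proportion))
    else:
        t = float(np.quantile(prob, target_proportion))
    t = float(np.clip(t, *t_bounds))
    if t >= 0.5:
        raise ValueError(f"derived threshold t={t} must be below 0.5")

    label = np.where(prob < t, "NegLFC", np.where(prob > 1.0 - t, "PosLFC", "NotDA"))
    return GroundTruth(
        p_da=truth.p_da,
        prob_c2=truth.prob_c2,
        w=truth.w,
        target_population=truth.target_population,
        t=t,
        label=pd.Series(label, index=truth.cell_ids, name="label"),
    )


def assign_conditions(
    dataset: MultiSampleDataset,
    truth: GroundTruth,
    n_replicates: int = 3,
    seed: int = 0,
    max_retries: int = 10,
) -> MultiSampleDataset:
    """Draw each cell's condition ~ Bernoulli(prob_c2) and a replicate.

    Produces exactly ``2 * n_replicates`` samples named ``C{1,2}_R{r}``.
    If any sample ends up empty the assignment is redrawn (logged), up
    to ``max_retries`` times.
    """
    prob = truth.prob_c2.loc[dataset.cell_ids].to_numpy()
    rng = _rng(seed, "conditions")
    n = dataset.n_cells
    for attempt in range(max_retries):
        cond = np.where(rng.random(n) < prob, "C2", "C1")
        rep = rng.integers(1, n_replicates + 1, n)
        sample = np.char.add(np.char.add(cond, "_R"), rep.astype(str))
        counts = pd.Series(sample).value_counts()
        # every replicate of every condition that occurs must be non-empty
        # (a degenerate prob vector may legitimately produce one condition)
        if len(counts) == n_replicates * len(np.unique(cond)):
            break
        logger.warning("empty sample on attempt %d; resampling", attempt + 1)
        warnings.warn("empty sample encountered; resampling conditions")
    else:
        raise RuntimeError("could not produce non-empty samples for every replicate")

    out = dataset.copy()
    out.cell_meta["condition"] = cond
    out.cell_meta["replicate"] = [f"R{r}" for r in rep]
    out.cell_meta["sample"] = sample
    return out


# ---------------------------------------------------------------------------
# batch effects and subsampling
# ---------------------------------------------------------------------------

def add_batch_effects(
    dataset: MultiSampleDataset,
    config: BatchConfig,
    embedding: str = "pca",
) -> MultiSampleDataset:
    """Assign cells to batches and shift each batch's PC profile.

    One Gaussian vector with i.i.d. N(0, batch_sd^2) entries is drawn per
    batch and added to the embedding of every cell in that batch.  The
    unshifted embedding is preserved as ``{embedding}_original``.
    """
    if embedding not in dataset.embeddings:
        raise ValueError(f"dataset has no {embedding!r} embedding")
    rng = _rng(config.seed, "batch")
    out = dataset.copy()
    n = out.n_cells
    batch_idx = rng.integers(0, config.n_batches, n)
    out.cell_meta["batch"] = [f"B{b + 1}" for b in batch_idx]

    coords = out.embeddings[embedding]
    out.embeddings[f"{embedding}_original"] = coords.copy()
    d = coords.shape[1]
    shifts = rng.normal(0.0, config.batch_sd, size=(config.n_batches, d))
    if config.batch_sd == 0:
        shifts[:] = 0.0
    out.embeddings[embedding] = coords + shifts[batch_idx]
    return out


def subsample_population(
    dataset: MultiSampleDataset,
    population: str,
    target_size: int,
    seed: int = 0,
) -> MultiSampleDataset:
    """Uniformly subsample one population to ``target_size`` cells."""
    in_pop = (dataset.cell_meta["population"] == population).to_numpy()
    current = int(in_pop.sum())
    if current == 0:
        raise ValueError(f"unknown or empty population {population!r}")
    if target_size > current:
        raise ValueError(f"target_size {target_size} exceeds population size {current}")
    rng = _rng(seed, "subsample")
    pop_idx = np.flatnonzero(in_pop)
    keep_pop = rng.choice(pop_idx, size=target_size, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(~in_pop), keep_pop]))
    return dataset.subset(keep)


def simulate_scaling_series(
    sizes: list[int], base_config: TopologyConfig
) -> list[MultiSampleDataset]:
    """One dataset per requested cell count, other parameters shared.

    Each dataset draws from its own RNG stream (seeded by size) so any
    single member is reproducible independently of the rest.  Intended
    for the timing harness only.
    """
    if any(s <= 0 for s in sizes):
        raise ValueError("sizes must be positive")
    out = []
    for s in sizes:
        cfg = TopologyConfig(
            kind=base_config.kind,
            n_cells=s,
            n_genes=base_config.n_genes,
            populations=None,
            dispersion=base_config.dispersion,
            expression_scale=base_config.expression_scale,
            seed=base_config.seed * 1000003 % (2**31) + s,
        )
        out.append(simulate_topology(cfg))
    return out
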