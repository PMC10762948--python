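"""Grid orchestration: simulate -> plant -> test -> score.

The benchmark grid is (topology x DA ratio x target population x seed x
method).  Topology simulation and graph construction depend only on
(topology, seed), so they are prepared once per seed and shared across
ratios, targets and methods; planting, condition assignment and the
optional batch injection happen per grid cell.
"""

from __future__ import annotations

import inspect
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import GroundTruth, MultiSampleDataset
from .evaluate import MetricRecord, records_frame, score_result
from .methods import METHODS, DAResult
from .preprocess import CellGraph, build_knn_graph, embed_dataset
from .simulate import (
    BatchConfig,
    TopologyConfig,
    add_batch_effects,
    assign_conditions,
    default_config,
    ground_truth_labels,
    plant_da,
    simulate_scaling_series,
    simulate_topology,
)

logger = logging.getLogger(__name__)

DEFAULT_RATIOS = (0.75, 0.85, 0.95)

DEFAULT_TARGETS = {
    "linear": ["L1", "L3", "L5"],
    "branch": ["T1", "A2", "B2"],
    "cluster": ["M1", "M2", "M3"],
}

DEFAULT_METHOD_PARAMS: dict[str, dict] = {
    "cydar": {"center_fraction": 0.1, "alpha": 0.1},
    "daseq": {"n_permutations": 50},
    "meld": {"beta": 60.0},
    "cna": {"steps": 3, "n_permutations": 1000, "fdr": 0.05},
    "milo": {"sample_fraction": 0.1, "alpha": 0.1},
    "louvain": {"resolution": 1.0, "alpha": 0.1},
}


@dataclass
class PreparedData:
    """A simulated topology with its PC embedding and kNN graph."""

    topology: str
    seed: int
    dataset: MultiSampleDataset
    graph: CellGraph


def prepare_base(
    topology: str,
    seed: int,
    n_cells: int | None = None,
    n_genes: int | None = None,
    n_components: int = 50,
    k: int = 90,
    kernel: str = "binary",
) -> PreparedData:
    """Simulate one topology and attach embedding + graph."""
    cfg = default_config(topology, seed=seed)
    if n_cells is not None or n_genes is not None:
        pops = None
        if topology == "cluster":
            n_cells = n_cells or cfg.n_cells
            # keep the shipped 1:2:1 imbalance at any size
            quarter = n_cells // 4
            pops = {"M1": quarter, "M2": n_cells - 2 * quarter, "M3": quarter}
        cfg = TopologyConfig(
            kind=topology,
            n_cells=n_cells or cfg.n_cells,
            n_genes=n_genes or cfg.n_genes,
            populations=pops,
            seed=seed,
        )
    dataset = simulate_topology(cfg)
    n_comp = min(n_components, dataset.n_cells - 1, dataset.n_genes)
    dataset = embed_dataset(dataset, n_components=n_comp)
    graph = build_knn_graph(dataset.embeddings["pca"], k=min(k, dataset.n_cells - 1), kernel=kernel)
    return PreparedData(topology=topology, seed=seed, dataset=dataset, graph=graph)


def plant_and_assign(
    base: PreparedData,
    target: str,
    p_da: float,
    seed: int,
    batch_sd: float = 0.0,
    k: int = 90,
    kernel: str = "binary",
) -> tuple[MultiSampleDataset, GroundTruth, CellGraph]:
    """Plant a DA effect, assign conditions and (optionally) batches.

    Ground truth is derived from the unshifted embedding; when batch
    effects are injected the kNN graph is rebuilt on the shifted
    embedding, as any real pipeline would see it.
    """
    truth = plant_da(base.dataset, target, p_da, seed=seed)
    share = float((base.dataset.cell_meta["population"] == target).mean())
    truth = ground_truth_labels(truth, target_proportion=share)
    ds = assign_conditions(base.dataset, truth, seed=seed)
    graph = base.graph
    if batch_sd > 0:
        ds = add_batch_effects(ds, BatchConfig(batch_sd=batch_sd, seed=seed))
        graph = build_knn_graph(ds.embeddings["pca"], k=min(k, ds.n_cells - 1), kernel=kernel)
    return ds, truth, graph


def make_method(name: str, dataset, graph, use_batch: bool = False, seed: int = 0, **params):
    """Instantiate a method by name, passing a seed where it applies."""
    if name not in METHODS:
        raise ValueError(f"unknown method {name!r}; available: {sorted(METHODS)}")
    cls = METHODS[name]
    kwargs = dict(params)
    if "seed" in inspect.signature(cls.__init__).parameters:
        kwargs.setdefault("seed", seed)
    return cls(dataset, graph, use_batch=use_batch, **kwargs)


def run_case(
    base: PreparedData,
    method: str,
    target: str,
    p_da: float,
    seed: int,
    batch_sd: float = 0.0,
    use_batch: bool = False,
    method_params: dict | None = None,
    k: int = 90,
    kernel: str = "binary",
) -> tuple[DAResult, GroundTruth]:
    ds, truth, graph = plant_and_assign(
        base, target, p_da, seed, batch_sd=batch_sd, k=k, kernel=kernel
    )
    params = dict(DEFAULT_METHOD_PARAMS.get(method, {}))
    params.update(method_params or {})
    model = make_method(method, ds, graph, use_batch=use_batch, seed=seed, **params)
    return model.fit(), truth


@dataclass
class GridSpec:
    """One benchmark grid: what to simulate and which methods to run."""

    topologies: list[str] = field(default_factory=lambda: ["linear", "branch", "cluster"])
    da_ratios: list[float] = field(default_factory=lambda: list(DEFAULT_RATIOS))
    targets: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2])
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    method_params: dict[str, dict] = field(default_factory=dict)
    n_cells: int | None = None
    n_genes: int | None = None
    n_components: int = 50
    k: int = 90
    kernel: str = "binary"
    batch_sd: float = 0.0
    use_batch: bool = False

    def cases(self):
        for topo in self.topologies:
            for seed in self.seeds:
                for target in self.targets.get(topo, DEFAULT_TARGETS[topo]):
                    for ratio in self.da_ratios:
                        yield topo, seed, target, ratio


def run_grid(
    spec: GridSpec,
    master_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Execute the full grid; one MetricRecord row per (case, method).

    Failures of a single (method, case) pair are logged and recorded as
    missing rows rather than aborting the grid.
    """
    records: list[MetricRecord] = []
    bases: dict[tuple[str, int], PreparedData] = {}
    for topo, seed, target, ratio in spec.cases():
        case_seed = (master_seed * 10007 + seed) % (2**31)
        key = (topo, seed)
        if key not in bases:
            bases[key] = prepare_base(
                topo,
                case_seed,
                n_cells=spec.n_cells,
                n_genes=spec.n_genes,
                n_components=spec.n_components,
                k=spec.k,
                kernel=spec.kernel,
            )
        base = bases[key]
        try:
            ds, truth, graph = plant_and_assign(
                base, target, ratio, case_seed,
                batch_sd=spec.batch_sd, k=spec.k, kernel=spec.kernel,
            )
        except Exception:
            logger.exception("planting failed for %s/%s/%s", topo, target, ratio)
            continue
        for method in spec.methods:
            params = dict(DEFAULT_METHOD_PARAMS.get(method, {}))
            params.update(spec.method_params.get(method, {}))
            try:
                model = make_method(
                    method, ds, graph, use_batch=spec.use_batch,
                    seed=case_seed, **params,
                )
                result = model.fit()
                rec = score_result(
                    result, truth,
                    dataset_name=topo, topology=topo, seed=seed,
                )
                records.append(rec)
                if progress:
                    print(
                        f"{method:8s} {topo:8s} target={target:3s} ratio={ratio} "
                        f"seed={seed} auroc={rec.auroc:.3f} auprc={rec.auprc:.3f}",
                        flush=True,
                    )
            except Exception:
                logger.exception(
                    "method %s failed on %s/%s/%s seed=%s",
                    method, topo, target, ratio, seed,
                )
    return records_frame(records)


def timing_table(
    sizes: list[int],
    methods: list[str],
    base_kind: str = "linear",
    n_genes: int = 100,
    seed: int = 0,
    method_params: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Wall time per method per dataset size, normalized to the smallest.

    Informational only: absolute numbers depend on hardware; the
    relative growth column mirrors how scalability is usually reported.
    """
    base_cfg = TopologyConfig(kind=base_kind, n_cells=max(sizes or [2]), n_genes=n_genes, seed=seed)
    datasets = simulate_scaling_series(sizes, base_cfg)
    rows = []
    for size, raw in zip(sizes, datasets):
        base = prepare_base(base_kind, seed, n_cells=size, n_genes=n_genes)
        target = DEFAULT_TARGETS[base_kind][0]
        ds, truth, graph = plant_and_assign(base, target, 0.95, seed)
        for method in methods:
            params = dict(DEFAULT_METHOD_PARAMS.get(method, {}))
            params.update((method_params or {}).get(method, {}))
            try:
                model = make_method(method, ds, graph, seed=seed, **params)
                t0 = time.perf_counter()
                model.fit()
                elapsed = time.perf_counter() - t0
            except Exception:
                logger.exception("timing failed for %s at n=%d", method, size)
                elapsed = np.nan
            rows.append({"method": method, "n_cells": size, "seconds": elapsed})
    frame = pd.DataFrame(rows)
    if not frame.empty:
        smallest = frame[frame["n_cells"] == min(sizes)].set_index("method")["seconds"]
        frame["relative_growth"] = frame.apply(
            lambda r: r["seconds"] / smallest.get(r["method"], np.nan), axis=1
        )
    return frame
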