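"""YAML benchmark configuration.

A config file mirrors :class:`~dabench.bench.GridSpec` in three blocks::

    simulate:
      topologies: [linear, branch, cluster]
      da_ratios: [0.75, 0.85, 0.95]
      targets: {linear: [L1, L3, L5]}
      seeds: [0, 1, 2]
      batch_sd: 0.0
      n_cells: null        # null = shipped per-topology defaults
      n_genes: null
    preprocess:
      n_components: 50
      k: 30
      kernel: binary
    methods:               # per-method hyperparameters; omit for defaults
      meld: {beta: 60.0}
      milo: {sample_fraction: 0.1, alpha: 0.1}
    use_batch: false
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .bench import DEFAULT_METHOD_PARAMS, GridSpec
from .methods import METHODS


def default_spec() -> GridSpec:
    """The shipped benchmark configuration (all six methods)."""
    return GridSpec(method_params={m: dict(p) for m, p in DEFAULT_METHOD_PARAMS.items()})


def spec_from_dict(raw: dict) -> GridSpec:
    spec = default_spec()
    sim = raw.get("simulate", {})
    for key in ("topologies", "da_ratios", "targets", "seeds", "batch_sd", "n_cells", "n_genes"):
        if key in sim and sim[key] is not None:
            setattr(spec, key, sim[key])
    pre = raw.get("preprocess", {})
    for key in ("n_components", "k", "kernel"):
        if key in pre and pre[key] is not None:
            setattr(spec, key, pre[key])
    if "methods" in raw and raw["methods"] is not None:
        methods = raw["methods"]
        unknown = set(methods) - set(METHODS)
        if unknown:
            raise ValueError(
                f"unknown methods {sorted(unknown)}; available: {sorted(METHODS)}"
            )
        spec.methods = list(methods)
        spec.method_params = {
            m: {**DEFAULT_METHOD_PARAMS.get(m, {}), **(params or {})}
            for m, params in methods.items()
        }
    spec.use_batch = bool(raw.get("use_batch", False))
    return spec


def load_config(path: str | Path) -> GridSpec:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return spec_from_dict(raw)


def dump_config(spec: GridSpec, path: str | Path) -> None:
    raw = {
        "simulate": {
            "topologies": spec.topologies,
            "da_ratios": spec.da_ratios,
            "targets": spec.targets,
            "seeds": spec.seeds,
            "batch_sd": spec.batch_sd,
            "n_cells": spec.n_cells,
            "n_genes": spec.n_genes,
        },
        "preprocess": {
            "n_components": spec.n_components,
            "k": spec.k,
            "kernel": spec.kernel,
        },
        "methods": {m: spec.method_params.get(m, {}) for m in spec.methods},
        "use_batch": spec.use_batch,
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
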