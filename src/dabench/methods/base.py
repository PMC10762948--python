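"""Model/Results scaffolding shared by the six DA testing methods.

Every method is a model class constructed from a
:class:`~dabench.datasets.MultiSampleDataset` (plus, for the graph-based
methods, a :class:`~dabench.preprocess.CellGraph`); calling ``fit()``
returns a :class:`DAResult` carrying per-cell DA scores/directions and
the per-unit (hypersphere / neighbourhood / cluster) test table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..datasets import MultiSampleDataset, write_manifest
from ..preprocess import CellGraph


@dataclass
class DAResult:
    """Per-cell DA scores plus the unit-level test table of one method.

    ``cell_table`` is indexed by cell id with columns ``score`` (higher =
    more differentially abundant; 0 and ``not_assessed`` for cells the
    method never covered), ``direction`` (+1 enriched in C2, -1 in C1, 0
    none), ``significant`` and ``not_assessed``.
    """

    method: str
    cell_table: pd.DataFrame
    unit_table: pd.DataFrame
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        scores = self.cell_table["score"].to_numpy()
        assessed = ~self.cell_table["not_assessed"].to_numpy()
        if not np.all(np.isfinite(scores[assessed])):
            raise ValueError("per-cell scores must be finite where assessed")
        for col in ("p_value", "spatial_fdr", "fdr"):
            if col in self.unit_table:
                vals = self.unit_table[col].to_numpy(dtype=float)
                ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
                if not np.all(ok):
                    raise ValueError(f"{col} must lie in [0, 1]")

    @property
    def scores(self) -> np.ndarray:
        return self.cell_table["score"].to_numpy(dtype=float)

    @property
    def directions(self) -> np.ndarray:
        return self.cell_table["direction"].to_numpy(dtype=float)

    @property
    def significant_cells(self) -> np.ndarray:
        return self.cell_table["significant"].to_numpy(dtype=bool)

    def summary(self) -> str:
        n = len(self.cell_table)
        n_sig = int(self.cell_table["significant"].sum())
        n_na = int(self.cell_table["not_assessed"].sum())
        lines = [
            f"DA testing results: {self.method}",
            "=" * 40,
            f"cells:                 {n}",
            f"testing units:         {len(self.unit_table)}",
            f"significant cells:     {n_sig} ({n_sig / n:.1%})",
            f"not assessed cells:    {n_na}",
            "hyperparameters:       "
            + ", ".join(f"{k}={v}" for k, v in self.hyperparams.items()),
        ]
        return "\n".join(lines)

    def save(self, outdir: str | Path, stem: str = "result") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cells = self.cell_table.copy()
        cells.insert(0, "method", self.method)
        cells.index.name = "cell_id"
        cells.to_csv(outdir / f"{stem}_cells.tsv", sep="\t")
        self.unit_table.to_csv(outdir / f"{stem}_units.tsv", sep="\t", index=False)
        write_manifest(
            outdir / f"{stem}_manifest.json",
            {
                "method": self.method,
                "hyperparams": {k: repr(v) for k, v in self.hyperparams.items()},
                "files": [f"{stem}_cells.tsv", f"{stem}_units.tsv"],
            },
        )


@dataclass
class GroupDesign:
    """Sample-level (or sample x batch pseudo-sample) design of a dataset."""

    codes: np.ndarray          # per-cell group index
    group_ids: list[str]
    condition: np.ndarray      # per-group 0 (C1) / 1 (C2)
    batch: np.ndarray | None   # per-group batch label, or None
    totals: np.ndarray         # cells per group

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    @property
    def log_offsets(self) -> np.ndarray:
        return np.log(self.totals)


def group_design(dataset: MultiSampleDataset, use_batch: bool = False) -> GroupDesign:
    grouping = dataset.grouping(use_batch=use_batch)
    group_ids = sorted(grouping.unique())
    index = {g: i for i, g in enumerate(group_ids)}
    codes = grouping.map(index).to_numpy()
    cond_per_cell = dataset.cell_meta["condition"].to_numpy()
    condition = np.zeros(len(group_ids), dtype=int)
    batch = np.empty(len(group_ids), dtype=object) if use_batch else None
    for g, i in index.items():
        first = np.flatnonzero(codes == i)[0]
        condition[i] = 1 if cond_per_cell[first] == "C2" else 0
        if use_batch:
            batch[i] = dataset.cell_meta["batch"].iloc[first]
    if condition.min() == condition.max():
        raise ValueError("dataset contains a single condition; no contrast to test")
    totals = np.bincount(codes, minlength=len(group_ids)).astype(float)
    return GroupDesign(codes, group_ids, condition, batch, totals)


def count_units(
    memberships: list[np.ndarray], codes: np.ndarray, n_groups: int
) -> np.ndarray:
    """units x groups cell counts from per-unit member index lists."""
    counts = np.zeros((len(memberships), n_groups), dtype=int)
    for u, members in enumerate(memberships):
        counts[u] = np.bincount(codes[members], minlength=n_groups)
    return counts


class DAMethod:
    """Base class: construct from data, ``fit()`` to obtain a DAResult."""

    name = "base"

    def __init__(
        self,
        dataset: MultiSampleDataset,
        graph: CellGraph | None = None,
        embedding: str = "pca",
        use_batch: bool = False,
    ):
        if not dataset.has_samples:
            raise ValueError("dataset has no condition/sample assignment yet")
        self.dataset = dataset
        self.graph = graph
        self.embedding = embedding
        self.use_batch = use_batch
        self.design = group_design(dataset, use_batch=use_batch)

    # subclasses override
    def fit(self) -> DAResult:  # pragma: no cover - abstract
        raise NotImplementedError

    def _coords(self) -> np.ndarray:
        if self.embedding not in self.dataset.embeddings:
            raise ValueError(f"dataset has no {self.embedding!r} embedding")
        return np.asarray(self.dataset.embeddings[self.embedding], dtype=float)

    def _require_graph(self) -> CellGraph:
        if self.graph is None:
            raise ValueError(f"{self.name} requires a cell graph")
        return self.graph

    def _cell_frame(
        self,
        score: np.ndarray,
        direction: np.ndarray,
        significant: np.ndarray,
        not_assessed: np.ndarray | None = None,
    ) -> pd.DataFrame:
        n = self.dataset.n_cells
        if not_assessed is None:
            not_assessed = np.zeros(n, dtype=bool)
        return pd.DataFrame(
            {
                "score": score,
                "direction": direction,
                "significant": significant,
                "not_assessed": not_assessed,
            },
            index=self.dataset.cell_ids,
        )
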