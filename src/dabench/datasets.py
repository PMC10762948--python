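"""Core data containers for multi-sample single-cell benchmarks.

A :class:`MultiSampleDataset` holds a cells x genes count matrix together
with per-cell metadata (population, sample, condition, replicate and,
optionally, batch) and named low-dimensional embeddings.  A
:class:`GroundTruth` records the planted per-cell probability of having
been generated under condition C2 plus the derived three-way DA label.

Serialization uses plain-text formats only: Matrix Market for counts and
TSV for metadata, so that datasets written by the command-line interface
can be inspected and versioned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

CONDITIONS = ("C1", "C2")
LABELS = ("NegLFC", "PosLFC", "NotDA")

META_COLUMNS = ["population", "sample", "condition", "replicate", "batch"]


@dataclass
class MultiSampleDataset:
    """Cells x genes counts with per-cell metadata and embeddings.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per cell.
    cell_meta
        DataFrame indexed by cell id.  Always carries ``population``;
        ``sample``/``condition``/``replicate`` appear once conditions have
        been assigned, ``batch`` once batch effects have been injected.
    gene_names
        One name per column of ``counts``.
    embeddings
        Named cells x d matrices, e.g. ``{"pca": ...}``.
    """

    counts: np.ndarray
    cell_meta: pd.DataFrame
    gene_names: list[str] = field(default_factory=list)
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if counts.shape[0] != len(self.cell_meta):
            raise ValueError("counts and cell_meta disagree on cell count")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        if not self.gene_names:
            self.gene_names = [f"G{j}" for j in range(counts.shape[1])]
        if len(self.gene_names) != counts.shape[1]:
            raise ValueError("gene_names length mismatch")
        self.counts = counts

    # -- basic shape -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def has_samples(self) -> bool:
        return "sample" in self.cell_meta.columns

    @property
    def has_batch(self) -> bool:
        return "batch" in self.cell_meta.columns

    @property
    def sample_ids(self) -> list[str]:
        if not self.has_samples:
            raise ValueError("conditions/samples have not been assigned yet")
        return sorted(self.cell_meta["sample"].unique())

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_table(self) -> pd.DataFrame:
        """One row per sample with its condition (and replicate)."""
        cols = [c for c in ("condition", "replicate") if c in self.cell_meta]
        tab = self.cell_meta.groupby("sample")[cols].first()
        return tab.loc[self.sample_ids]

    def populations(self) -> list[str]:
        return sorted(self.cell_meta["population"].unique())

    # -- grouping used by count-based tests ------------------------------
    def grouping(self, use_batch: bool = False) -> pd.Series:
        """Per-cell observational unit: sample, or sample x batch.

        When ``use_batch`` is set, each (sample, batch) combination is a
        separate pseudo-sample so downstream GLMs can carry a batch
        covariate; batch labels here are per-cell, not per-donor.
        """
        if use_batch:
            if not self.has_batch:
                raise ValueError("dataset carries no batch labels")
            return (
                self.cell_meta["sample"].astype(str)
                + "|"
                + self.cell_meta["batch"].astype(str)
            )
        return self.cell_meta["sample"].astype(str)

    # -- subsetting ------------------------------------------------------
    def subset(self, mask: np.ndarray) -> "MultiSampleDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return MultiSampleDataset(
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_names=list(self.gene_names),
            embeddings={k: v[idx] for k, v in self.embeddings.items()},
        )

    def copy(self) -> "MultiSampleDataset":
        return MultiSampleDataset(
            counts=self.counts.copy(),
            cell_meta=self.cell_meta.copy(),
            gene_names=list(self.gene_names),
            embeddings={k: v.copy() for k, v in self.embeddings.items()},
        )

    # -- interop ---------------------------------------------------------
    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (counts in ``.X``)."""
        import anndata as ad

        adata = ad.AnnData(
            X=sparse.csr_matrix(self.counts),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        for name, emb in self.embeddings.items():
            adata.obsm[f"X_{name}"] = np.asarray(emb)
        return adata

    # -- plain-text serialization ----------------------------------------
    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(outdir / "counts.mtx", sparse.coo_matrix(self.counts))
        meta = self.cell_meta.copy()
        meta.index.name = "cell_id"
        meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
        pd.Series(self.gene_names, name="gene").to_csv(
            outdir / "genes.tsv", sep="\t", index=False
        )
        for name, emb in self.embeddings.items():
            np.savetxt(outdir / f"embedding_{name}.tsv", emb, delimiter="\t")

    @classmethod
    def load(cls, indir: str | Path) -> "MultiSampleDataset":
        indir = Path(indir)
        counts = np.asarray(spio.mmread(indir / "counts.mtx").todense())
        meta = pd.read_csv(indir / "cell_meta.tsv", sep="\t", index_col=0)
        genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene"].tolist()
        embeddings = {}
        for f in sorted(indir.glob("embedding_*.tsv")):
            name = f.stem.removeprefix("embedding_")
            embeddings[name] = np.loadtxt(f, delimiter="\t")
        return cls(counts, meta, genes, embeddings)


@dataclass
class GroundTruth:
    """Planted per-cell condition-C2 probability and derived DA labels.

    ``prob_c2`` follows the min-max rescaling of the logit-transformed
    centroid similarity ``w`` onto ``[0.5, p_da]`` (or ``[p_da, 0.5]`` for
    a depletion with ``p_da < 0.5``).  Labels are assigned by a symmetric
    threshold ``t``: NegLFC below ``t``, PosLFC above ``1 - t``, NotDA in
    between.
    """

    p_da: float
    prob_c2: pd.Series
    w: pd.Series
    target_population: str
    t: float | None = None
    label: pd.Series | None = None

    @property
    def cell_ids(self) -> pd.Index:
        return self.prob_c2.index

    def positive_mask(self) -> np.ndarray:
        """Boolean vector: DA (PosLFC or NegLFC) vs NotDA."""
        if self.label is None:
            raise ValueError("labels not assigned yet")
        return (self.label != "NotDA").to_numpy()

    def subset(self, cell_ids: pd.Index) -> "GroundTruth":
        return GroundTruth(
            p_da=self.p_da,
            prob_c2=self.prob_c2.loc[cell_ids],
            w=self.w.loc[cell_ids],
            target_population=self.target_population,
            t=self.t,
            label=None if self.label is None else self.label.loc[cell_ids],
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "prob_c2": self.prob_c2,
                "w": self.w,
                "label": self.label if self.label is not None else "unset",
            }
        )
        frame["p_da"] = self.p_da
        frame["t"] = np.nan if self.t is None else self.t
        frame["target_population"] = self.target_population
        frame.index.name = "cell_id"
        return frame

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        label = frame["label"]
        return cls(
            p_da=float(frame["p_da"].iloc[0]),
            prob_c2=frame["prob_c2"],
            w=frame["w"],
            target_population=str(frame["target_population"].iloc[0]),
            t=None if frame["t"].isna().all() else float(frame["t"].iloc[0]),
            label=None if (label == "unset").all() else label,
        )


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
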