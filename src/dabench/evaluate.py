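"""Percentile-threshold AUROC/AUPRC scoring against planted ground truth.

Every method's per-cell DA scores are swept over thresholds placed at
the 0..100 percentiles (1% steps) of its own score distribution; at
each threshold cells scoring at or above are predicted DA.  Both
PosLFC and NegLFC count as the positive class.  ROC points are anchored
at (0,0) and (1,1) and integrated by the trapezoid rule; PR curves
carry the highest-threshold precision down to recall 0.  Records are
aggregated the benchmark's way: median over (target population x seed)
within each DA ratio, then the mean of the per-ratio medians.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .datasets import GroundTruth


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricRecord:
    """One (method, dataset, DA ratio, target, seed) benchmark outcome."""

    method: str
    dataset: str
    topology: str
    da_ratio: float
    target_population: str
    seed: int
    auroc: float
    auprc: float
    n_cells: int

    def to_dict(self) -> dict:
        return asdict(self)


def binarize_truth(labels) -> np.ndarray:
    """Positive iff the label is PosLFC or NegLFC (i.e. not NotDA)."""
    arr = np.asarray(labels)
    bad = set(np.unique(arr)) - {"NegLFC", "PosLFC", "NotDA"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return arr != "NotDA"


def threshold_grid(scores: np.ndarray, percentiles: np.ndarray | None = None) -> np.ndarray:
    """Thresholds at the given percentiles (default 0..100 step 1)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    if percentiles is None:
        percentiles = np.arange(0, 101)
    return np.percentile(scores, percentiles)


def confusion_at(
    scores: np.ndarray, truth_binary: np.ndarray, threshold: float
) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth_binary, dtype=bool)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != truth.shape:
        raise ValueError("scores and truth lengths differ")
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def fpr_tpr(c: ConfusionCounts) -> tuple[float, float]:
    if c.fp + c.tn == 0 or c.tp + c.fn == 0:
        raise ValueError("a truth class is missing; rates undefined")
    return c.fp / (c.fp + c.tn), c.tp / (c.tp + c.fn)


def _sweep(scores, truth):
    thresholds = threshold_grid(scores)
    return [confusion_at(scores, truth, t) for t in np.unique(thresholds)]


def auroc(scores: np.ndarray, truth_binary: np.ndarray) -> float:
    """Grid-protocol area under the ROC curve."""
    truth = np.asarray(truth_binary, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("AUROC needs both truth classes")
    pts = [fpr_tpr(c) for c in _sweep(scores, truth)]
    pts += [(0.0, 0.0), (1.0, 1.0)]
    pts = sorted(set(pts))
    xs, ys = zip(*pts)
    return float(np.trapezoid(ys, xs))


def auprc(scores: np.ndarray, truth_binary: np.ndarray) -> float:
    """Grid-protocol area under the precision-recall curve.

    Precision at recall -> 0 is carried over from the highest-threshold
    point, a convention that keeps the constant-score baseline equal to
    the prevalence.
    """
    truth = np.asarray(truth_binary, dtype=bool)
    if not truth.any():
        raise ValueError("AUPRC needs at least one positive")
    # sweep thresholds from high to low: recall is then non-decreasing
    thresholds = np.unique(threshold_grid(scores))[::-1]
    pts = []
    for t in thresholds:
        c = confusion_at(scores, truth, t)
        if c.tp + c.fp == 0:
            continue
        pts.append((c.tp / (c.tp + c.fn), c.tp / (c.tp + c.fp)))
    # carry the highest-threshold precision down to recall 0
    pts = [(0.0, pts[0][1])] + pts
    xs, ys = zip(*pts)
    return float(np.trapezoid(ys, xs))


def score_result(
    result,
    truth: GroundTruth,
    dataset_name: str,
    topology: str,
    seed: int,
    strict_direction: bool = False,
) -> MetricRecord:
    """Score one DAResult against the planted labels.

    By default direction is ignored (binary DA vs NotDA).  With
    ``strict_direction`` a cell whose reported direction contradicts its
    planted label sign is scored 0, so only correctly-signed evidence
    can count as a detection.
    """
    scores = result.scores.copy()
    scores[result.cell_table["not_assessed"].to_numpy()] = 0.0
    truth_binary = truth.positive_mask()
    if strict_direction:
        label_sign = truth.label.map(
            {"PosLFC": 1.0, "NegLFC": -1.0, "NotDA": 0.0}
        ).to_numpy()
        contradicted = (label_sign != 0) & (result.directions * label_sign < 0)
        scores[contradicted] = 0.0
    return MetricRecord(
        method=result.method,
        dataset=dataset_name,
        topology=topology,
        da_ratio=truth.p_da,
        target_population=truth.target_population,
        seed=seed,
        auroc=auroc(scores, truth_binary),
        auprc=auprc(scores, truth_binary),
        n_cells=len(scores),
    )


RECORD_COLUMNS = [
    "method",
    "dataset",
    "topology",
    "da_ratio",
    "target_population",
    "seed",
    "auroc",
    "auprc",
    "n_cells",
]


def records_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records], columns=RECORD_COLUMNS)


def aggregate(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benchmark aggregation of metric records.

    Returns ``(per_ratio, summary)``: the median AUROC/AUPRC over
    (target population x seed) within each (method, dataset, DA ratio),
    and the mean of those per-ratio medians per (method, dataset).
    Empty inputs yield empty frames.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if frame.empty:
        empty = pd.DataFrame(columns=["method", "dataset", "auroc", "auprc"])
        return empty.copy(), empty
    per_ratio = (
        frame.groupby(["method", "dataset", "da_ratio"], as_index=False)[
            ["auroc", "auprc"]
        ].median()
    )
    summary = (
        per_ratio.groupby(["method", "dataset"], as_index=False)[
            ["auroc", "auprc"]
        ].mean()
    )
    return per_ratio, summary
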