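"""Eight-metric evaluation, allele-frequency strata, tool comparison.

Threshold metrics (accuracy, precision, sensitivity/recall, specificity,
F1, MCC) follow the textbook confusion-count formulas; a metric whose
denominator is zero is reported as missing rather than NaN-propagated.
AUC is the tie-corrected Mann-Whitney pairwise concordance; AUPRC is the
area under the step-wise precision-recall curve (no linear interpolation
between operating points). Variants a tool does not score are excluded
from that tool's metrics and surfaced as a missing rate, so tools with
different coverage stay comparable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

METRIC_NAMES = (
    "accuracy",
    "precision",
    "sensitivity",
    "specificity",
    "f1",
    "mcc",
    "auc",
    "auprc",
)

#: Default allele-frequency strata (half-open; last bin closed at 1).
DEFAULT_AF_BINS = (
    (0.0, 1e-4),
    (1e-4, 1e-3),
    (1e-3, 1e-2),
    (1e-2, 1e-1),
    (1e-1, 1.0),
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass
class MetricReport:
    """The eight metrics plus confusion counts and coverage bookkeeping."""

    accuracy: Optional[float] = None
    precision: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    f1: Optional[float] = None
    mcc: Optional[float] = None
    auc: Optional[float] = None
    auprc: Optional[float] = None
    confusion: Optional[ConfusionCounts] = None
    n_scored: int = 0
    n_missing: int = 0

    @property
    def missing_rate(self) -> float:
        total = self.n_scored + self.n_missing
        return self.n_missing / total if total else 0.0

    def as_dict(self) -> dict:
        out = {name: getattr(self, name) for name in METRIC_NAMES}
        out.update(
            n_scored=self.n_scored,
            n_missing=self.n_missing,
            missing_rate=self.missing_rate,
        )
        if self.confusion is not None:
            out.update(
                tp=self.confusion.tp,
                fp=self.confusion.fp,
                tn=self.confusion.tn,
                fn=self.confusion.fn,
            )
        return out


@dataclass
class AFStratumReport:
    af_bin: tuple  # (low, high), half-open except the last
    report: MetricReport = field(default_factory=MetricReport)
    n: int = 0


def confusion(labels: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    """Exact confusion counts for binary labels (1 = pathogenic)."""
    labels = np.asarray(labels, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != predicted.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((labels == 1) & (predicted == 1)))
    fp = int(np.sum((labels == 0) & (predicted == 1)))
    tn = int(np.sum((labels == 0) & (predicted == 0)))
    fn = int(np.sum((labels == 1) & (predicted == 0)))
    return ConfusionCounts(tp, fp, tn, fn)


def _safe_div(num: float, den: float) -> Optional[float]:
    return num / den if den else None


def threshold_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, sensitivity, specificity, F1 and MCC."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    accuracy = _safe_div(tp + tn, counts.total)
    precision = _safe_div(tp, tp + fp)
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    denom = (
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (
        (float(tp) * tn - float(fp) * fn) / math.sqrt(denom) if denom else None
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
        "mcc": mcc,
    }


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> Optional[float]:
    """Tie-corrected Mann-Whitney AUC: P(score+ > score-) + ties/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        warnings.warn("roc_auc needs both classes; returning missing")
        return None
    ranks = rankdata(scores)  # average ranks for ties
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> Optional[float]:
    """Area under the step-wise precision-recall curve.

    Operating points are the distinct score values in descending order;
    the area is the sum of precision times recall increments (no linear
    interpolation between points).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0 or int(np.sum(labels == 0)) == 0:
        warnings.warn("pr_auc needs both classes; returning missing")
        return None
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    area = 0.0
    prev_recall = 0.0
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            tp += labels[j] == 1
            fp += labels[j] == 0
            j += 1
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def _score_mask(scores) -> np.ndarray:
    arr = np.array(
        [np.nan if s is None else float(s) for s in scores], dtype=float
    )
    return arr, ~np.isnan(arr)


def _report(
    scores: np.ndarray, labels: np.ndarray, threshold: float, n_missing: int
) -> MetricReport:
    rep = MetricReport(n_scored=int(len(scores)), n_missing=n_missing)
    if len(scores) == 0:
        return rep
    predicted = (scores >= threshold).astype(int)
    counts = confusion(labels, predicted)
    rep.confusion = counts
    for name, value in threshold_metrics(counts).items():
        setattr(rep, name, value)
    if len(np.unique(labels)) == 2:
        rep.auc = roc_auc(scores, labels)
        rep.auprc = pr_auc(scores, labels)
    return rep


def evaluate(
    scores: Sequence,
    labels: Sequence[int],
    threshold: float = 0.5,
    af_values: Optional[Sequence] = None,
    af_bins: Sequence[tuple] = DEFAULT_AF_BINS,
) -> tuple:
    """Overall MetricReport plus per-AF-stratum reports.

    Missing scores (None/NaN) are excluded from every metric and counted
    into the missing rate. ``af_values`` may contain missing entries;
    those samples are excluded from the strata (but not from the overall
    report). The classification boundary is ``score >= threshold``.
    """
    scores_arr, scored = _score_mask(scores)
    labels_arr = np.asarray(labels, dtype=int)
    n_missing = int(np.sum(~scored))
    overall = _report(
        scores_arr[scored], labels_arr[scored], threshold, n_missing
    )

    strata = []
    if af_values is not None:
        af_arr = np.array(
            [np.nan if a is None else float(a) for a in af_values], dtype=float
        )
        last = len(af_bins) - 1
        for b, (lo, hi) in enumerate(af_bins):
            if b == last:
                in_bin = (af_arr >= lo) & (af_arr <= hi)
            else:
                in_bin = (af_arr >= lo) & (af_arr < hi)
            sel = in_bin & ~np.isnan(af_arr)
            n_bin = int(np.sum(sel))
            sel_scored = sel & scored
            rep = _report(
                scores_arr[sel_scored],
                labels_arr[sel_scored],
                threshold,
                int(np.sum(sel & ~scored)),
            )
            strata.append(AFStratumReport(af_bin=(lo, hi), report=rep, n=n_bin))
    return overall, strata


def compare_tools(
    score_table: pd.DataFrame,
    thresholds: dict,
    labels: Sequence[int],
) -> dict:
    """One MetricReport per tool column, honoring per-tool score direction.

    ``thresholds`` maps tool name to either a number (higher score =
    pathogenic) or a ``(threshold, direction)`` pair with direction in
    {"higher", "lower"}. Tools without a threshold entry get AUC/AUPRC
    only. Empty cells count into the tool's missing rate.
    """
    labels_arr = np.asarray(labels, dtype=int)
    reports = {}
    for tool in score_table.columns:
        raw = score_table[tool].to_numpy(dtype=float)
        spec = thresholds.get(tool)
        direction = "higher"
        thr = None
        if spec is not None:
            thr, direction = spec if isinstance(spec, (tuple, list)) else (spec, "higher")
        scores = -raw if direction == "lower" else raw
        scored = ~np.isnan(scores)
        n_missing = int(np.sum(~scored))
        if thr is not None:
            eff_thr = -thr if direction == "lower" else thr
            rep = _report(scores[scored], labels_arr[scored], eff_thr, n_missing)
        else:
            rep = MetricReport(n_scored=int(np.sum(scored)), n_missing=n_missing)
            if np.sum(scored) and len(np.unique(labels_arr[scored])) == 2:
                rep.auc = roc_auc(scores[scored], labels_arr[scored])
                rep.auprc = pr_auc(scores[scored], labels_arr[scored])
        reports[tool] = rep
    return reports


def score_distribution(
    scores: Sequence[float],
    labels: Sequence[int],
    n_bins: int = 20,
    threshold: float = 0.5,
) -> dict:
    """Per-class score histograms and a bimodality summary.

    Returns bin edges on [0,1], per-class counts, and the fraction of each
    class on its correct side of the threshold (pathogenic >= threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    pos, neg = scores[labels == 1], scores[labels == 0]
    hist_pos, _ = np.histogram(pos, bins=edges)
    hist_neg, _ = np.histogram(neg, bins=edges)
    return {
        "bin_edges": edges,
        "pathogenic_counts": hist_pos,
        "benign_counts": hist_neg,
        "threshold": threshold,
        "pathogenic_correct_fraction": (
            float(np.mean(pos >= threshold)) if len(pos) else None
        ),
        "benign_correct_fraction": (
            float(np.mean(neg < threshold)) if len(neg) else None
        ),
    }
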