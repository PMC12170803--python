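"""Optional report figures (ROC, score distribution, metric radar)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from prp.evaluation import METRIC_NAMES, score_distribution


def roc_plot(scores, labels, path):
    """ROC curve from raw scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores)
    labels_sorted = labels[order]
    tpr = np.concatenate([[0.0], np.cumsum(labels_sorted == 1) / max(np.sum(labels == 1), 1)])
    fpr = np.concatenate([[0.0], np.cumsum(labels_sorted == 0) / max(np.sum(labels == 0), 1)])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, color="crimson")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def distribution_plot(scores, labels, path, threshold: float = 0.5):
    """Per-class score densities with the decision threshold marked."""
    dist = score_distribution(scores, labels, threshold=threshold)
    centers = 0.5 * (dist["bin_edges"][:-1] + dist["bin_edges"][1:])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(centers, dist["pathogenic_counts"], color="darkorange", label="pathogenic")
    ax.plot(centers, dist["benign_counts"], color="steelblue", label="benign")
    ax.axvline(threshold, color="red", lw=1)
    ax.set_xlabel("prediction score")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def radar_plot(report, path):
    """Eight-metric radar of a MetricReport."""
    values = [getattr(report, m) or 0.0 for m in METRIC_NAMES]
    angles = np.linspace(0, 2 * np.pi, len(METRIC_NAMES), endpoint=False)
    values = values + values[:1]
    angles = np.concatenate([angles, angles[:1]])
    fig, ax = plt.subplots(figsize=(4.5, 4.5), subplot_kw={"polar": True})
    ax.plot(angles, values, color="crimson")
    ax.fill(angles, values, color="crimson", alpha=0.2)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(METRIC_NAMES, fontsize=8)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
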