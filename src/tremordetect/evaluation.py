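"""Evaluation metrics and model x modality comparison reports.

Five scores are derived from the binary confusion counts, with Tremor as
the positive class:

    precision   = TP / (TP + FP)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    f1          = 2 * precision * recall / (precision + recall)

A ratio with a zero denominator is reported as 0 and flagged, so reports
are total functions of the predictions.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import NO_TREMOR, TREMOR
from .types import ConfusionCounts, MetricsReport

METRIC_NAMES = ("precision", "accuracy", "recall", "specificity", "f1")


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Binary confusion counts (Tremor = positive class)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr in (y_true, y_pred):
        if arr.size and not np.isin(arr, (TREMOR, NO_TREMOR)).all():
            raise ValueError("labels must be binary (0 = No Tremor, 1 = Tremor)")
    tp = int(np.sum((y_true == TREMOR) & (y_pred == TREMOR)))
    tn = int(np.sum((y_true == NO_TREMOR) & (y_pred == NO_TREMOR)))
    fp = int(np.sum((y_true == NO_TREMOR) & (y_pred == TREMOR)))
    fn = int(np.sum((y_true == TREMOR) & (y_pred == NO_TREMOR)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts, model: str = "", modality: str = "") -> MetricsReport:
    """The five scores from confusion counts (zero-denominator rule: 0 + flag)."""
    flags = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = ratio(c.tp, c.tp + c.fp, "precision")
    recall = ratio(c.tp, c.tp + c.fn, "recall")
    specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    accuracy = ratio(c.tp + c.tn, c.n, "accuracy")
    f1 = ratio_f1(precision, recall, flags)
    return MetricsReport(counts=c, precision=precision, accuracy=accuracy,
                         recall=recall, specificity=specificity, f1=f1,
                         model=model, modality=modality,
                         zero_division_flags=tuple(flags))


def ratio_f1(precision: float, recall: float,
             flags: Optional[list] = None) -> float:
    if precision + recall == 0:
        if flags is not None:
            flags.append("f1")
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate(y_true, y_pred, model: str = "", modality: str = "") -> MetricsReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(y_true, y_pred), model=model, modality=modality)


def compare_report(reports: Iterable[MetricsReport]) -> dict:
    """Aggregate per-model/per-modality score tables.

    Returns a dict with:

    ``scores``  — tidy DataFrame, one row per (model, modality) with the
    five metrics; ``f1_matrix`` — model x modality pivot of f1;
    ``by_model`` / ``by_modality`` — mean +- SD of f1 across modalities per
    model and across models per modality (population SD, recorded in the
    table's ``sd_normalization`` attribute).
    """
    reports = list(reports)
    if not reports:
        raise ValueError("empty report collection")
    keys = [(r.model, r.modality) for r in reports]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (model, modality) keys in reports")
    rows = [{"model": r.model, "modality": r.modality,
             **{m: getattr(r, m) for m in METRIC_NAMES}} for r in reports]
    scores = pd.DataFrame(rows)
    f1_matrix = scores.pivot(index="model", columns="modality", values="f1")

    def _agg(group_col: str) -> pd.DataFrame:
        g = scores.groupby(group_col)["f1"]
        out = pd.DataFrame({"mean_f1": g.mean(), "sd_f1": g.std(ddof=0),
                            "n": g.size()})
        out.attrs["sd_normalization"] = "population (ddof=0)"
        return out

    return {"scores": scores, "f1_matrix": f1_matrix,
            "by_model": _agg("model"), "by_modality": _agg("modality")}


def plot_report(report: dict, out_prefix: str) -> list[str]:
    """Grouped metric bars per modality and an f1 heat map.

    Writes ``<out_prefix>_metrics.png`` and ``<out_prefix>_f1.png``;
    returns the paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores: pd.DataFrame = report["scores"]
    modalities = list(scores["modality"].unique())
    fig, axes = plt.subplots(1, len(modalities),
                             figsize=(4.5 * len(modalities), 3.5),
                             squeeze=False)
    for ax, mod in zip(axes[0], modalities):
        sub = scores[scores["modality"] == mod].set_index("model")
        sub[list(METRIC_NAMES[:-1])].plot.bar(ax=ax, rot=0, legend=(mod == modalities[0]))
        ax.set_ylim(0, 1.05)
        ax.set_title(mod)
        ax.set_ylabel("score")
    fig.tight_layout()
    p1 = f"{out_prefix}_metrics.png"
    fig.savefig(p1, dpi=120)
    plt.close(fig)

    f1 = report["f1_matrix"]
    fig, ax = plt.subplots(figsize=(1.6 * f1.shape[1] + 2, 1.0 * f1.shape[0] + 1.5))
    im = ax.imshow(f1.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(f1.shape[1]), f1.columns)
    ax.set_yticks(range(f1.shape[0]), f1.index)
    for i in range(f1.shape[0]):
        for j in range(f1.shape[1]):
            v = f1.values[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                        color="white" if v < 0.6 else "black")
    fig.colorbar(im, ax=ax, label="f1")
    ax.set_title("f1 by model and input modality")
    fig.tight_layout()
    p2 = f"{out_prefix}_f1.png"
    fig.savefig(p2, dpi=120)
    plt.close(fig)
    return [p1, p2]
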