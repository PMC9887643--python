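"""Evaluation: AUCROC, threshold metrics, attention binning, distributions.

AUCROC is rank-based (Mann-Whitney with midrank tie handling). Confusion
rates are reported at classification thresholds 0.5, 0.9 and 0.95 by default;
a score greater than or equal to the threshold counts as a positive call.
Attention maps are summarized by summing the per-position weights every eight
positions, which conserves each head's total attention mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model import AttentionMap
from .train import PairStore, predict_logits

__all__ = [
    "DEFAULT_THRESHOLDS",
    "roc_auc",
    "confusion_rates",
    "MetricReport",
    "evaluate_folds",
    "BinnedAttention",
    "bin_attention",
    "prediction_distributions",
]

DEFAULT_THRESHOLDS = (0.5, 0.9, 0.95)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; requires both classes present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def confusion_rates(scores, labels, threshold: float) -> dict:
    """TPR/FPR/TNR/FNR (normalized within true class), accuracy and F1 at a
    threshold; score >= threshold counts as a positive call."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    calls = scores >= threshold
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    tn = int(np.sum(~calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    tpr = tp / n_pos if n_pos else np.nan
    fnr = fn / n_pos if n_pos else np.nan
    tnr = tn / n_neg if n_neg else np.nan
    fpr = fp / n_neg if n_neg else np.nan
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * tpr / (precision + tpr)
          if (precision + tpr) > 0 and n_pos else 0.0)
    return {"threshold": threshold, "TP": tp, "FP": fp, "TN": tn, "FN": fn,
            "TPR": tpr, "FPR": fpr, "TNR": tnr, "FNR": fnr,
            "sensitivity": tpr, "specificity": tnr,
            "accuracy": (tp + tn) / len(labels) if len(labels) else np.nan,
            "F1": f1}


@dataclass
class MetricReport:
    """Per-fold metrics: AUCROC, accuracy and F1 at 0.5, and confusion rates
    at each requested threshold."""

    fold: str
    n_pairs: int
    aucroc: float
    accuracy: float
    f1: float
    per_threshold: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _score_table(model, store: PairStore, table) -> tuple:
    mi, pi, y = store.pairs_from_table(table)
    logits = predict_logits(model, store, mi, pi)
    return 1.0 / (1.0 + np.exp(-logits)), y


def evaluate_folds(model, store: PairStore, folds: dict,
                   thresholds=DEFAULT_THRESHOLDS, outdir=None) -> dict:
    """MetricReport per fold; each fold's table must already carry both
    labels (positives plus attached negatives)."""
    reports = {}
    rows = []
    for name, table in folds.items():
        frame = table.frame if hasattr(table, "frame") else table
        if len(frame) == 0:
            continue
        if set(frame["label"].unique()) != {0, 1}:
            raise ValueError(f"fold {name!r} lacks attached negatives")
        scores, y = _score_table(model, store, table)
        at_half = confusion_rates(scores, y, 0.5)
        rep = MetricReport(
            fold=name, n_pairs=len(y), aucroc=roc_auc(scores, y),
            accuracy=at_half["accuracy"], f1=at_half["F1"],
            per_threshold=[confusion_rates(scores, y, t) for t in thresholds])
        reports[name] = rep
        for t in rep.per_threshold:
            rows.append({"fold": name, "aucroc": rep.aucroc, **t})
    if outdir is not None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        with open(outdir / "metrics.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in reports.items()}, fh, indent=1)
    return reports


@dataclass
class BinnedAttention:
    head: int
    bins: np.ndarray
    bin_size: int
    metabolite_id: str = ""
    protein_id: str = ""


def bin_attention(amap: AttentionMap, bin_size: int = 8) -> BinnedAttention:
    """Sum attention weights over contiguous non-overlapping windows.

    The sequence length must be divisible by ``bin_size``; the per-head total
    mass is conserved exactly.
    """
    n = len(amap.alpha)
    if n % bin_size:
        raise ValueError(f"sequence length {n} not divisible by bin size {bin_size}")
    bins = amap.alpha.reshape(n // bin_size, bin_size).sum(axis=1)
    return BinnedAttention(head=amap.head, bins=bins, bin_size=bin_size,
                           metabolite_id=amap.metabolite_id,
                           protein_id=amap.protein_id)


def attention_heatmap(binned: list, path) -> None:
    """Optional visualization: heads x bins heatmap of summed attention."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.stack([b.bins for b in binned])
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(binned) + 1.5))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_xlabel(f"sequence bin ({binned[0].bin_size} positions)")
    ax.set_ylabel("attention head")
    fig.colorbar(im, ax=ax, label="summed attention")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def prediction_distributions(model, store: PairStore, protein_ids: list,
                             metabolite_sets: dict) -> pd.DataFrame:
    """Predicted probabilities of each metabolite set across a protein panel.

    Returns one row per set with mean, standard error and the raw samples
    (violin-ready), e.g. for comparing promiscuous against specific binders.
    """
    if not protein_ids:
        raise ValueError("empty protein panel")
    rows = []
    pidx = np.array([store.prot_index[p] for p in protein_ids])
    for name, mets in metabolite_sets.items():
        samples = []
        for m in mets:
            midx = np.full(len(pidx), store.met_index[m])
            logits = predict_logits(model, store, midx, pidx)
            samples.append(1.0 / (1.0 + np.exp(-logits)))
        flat = np.concatenate(samples)
        rows.append({"set": name, "n": len(flat), "mean": float(flat.mean()),
                     "sem": float(flat.std(ddof=1) / np.sqrt(len(flat)))
                     if len(flat) > 1 else 0.0,
                     "samples": flat})
    return pd.DataFrame(rows).set_index("set")
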