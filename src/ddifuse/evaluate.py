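"""Evaluation protocol: balanced sampling, confusion metrics, AUC/AUPR.

Threshold metrics come straight from the confusion counts:

    Acc  = (TP+TN) / (TP+TN+FP+FN)        Prec = TP / (TP+FP)
    Sen  = TP / (TP+FN)                    F1  = 2 Prec Sen / (Prec+Sen)
    MCC  = (TP TN - FP FN) / sqrt((TP+FP)(TN+FN)(TN+FP)(TP+FN))

AUC is computed as the Mann-Whitney rank statistic (ties count one half),
which is exactly the pairwise-comparison definition; AUPR is the
step-integrated area under the precision-recall curve.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata


@dataclass
class MetricsReport:
    """Classification metrics from one set of labels and scores."""

    acc: float
    prec: float
    sen: float
    f1: float
    mcc: float
    auc: float
    aupr: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return asdict(self)


def auc_rank(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC by the rank statistic; tied scores contribute one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def average_precision(labels: np.ndarray, scores: np.ndarray) -> float:
    """Step-integrated area under the precision-recall curve.

    AP = sum_i (R_i - R_{i-1}) P_i over distinct score thresholds in
    decreasing order.
    """
    labels = np.asarray(labels, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = labels.sum()
    if n_pos == 0 or n_pos == len(labels):
        return float("nan")
    order = np.argsort(-scores, kind="stable")
    ys = labels[order]
    ss = scores[order]
    distinct = np.where(np.diff(ss) != 0)[0]
    idx = np.r_[distinct, len(ss) - 1]
    tps = np.cumsum(ys)[idx]
    fps = (idx + 1) - tps
    precision = tps / (tps + fps)
    recall = tps / n_pos
    prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev) * precision))


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full metrics report from labels and probability scores.

    With a single class present, AUC, AUPR and MCC are reported as NaN
    (undefined) and the threshold metrics are still computed.  MCC with a
    zero denominator (a degenerate confusion matrix with both classes
    present) is reported as 0.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    sen = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * prec * sen / (prec + sen)) if (prec + sen) else 0.0

    single_class = (labels == labels[0]).all() if len(labels) else True
    if single_class:
        warnings.warn("single-class input: AUC/AUPR/MCC undefined")
        mcc = auc = aupr = float("nan")
    else:
        denom = math.sqrt(float(tp + fp) * (tn + fn) * (tn + fp) * (tp + fn))
        mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
        auc = auc_rank(labels, scores)
        aupr = average_precision(labels, scores)
    return MetricsReport(acc=acc, prec=prec, sen=sen, f1=f1, mcc=mcc,
                         auc=auc, aupr=aupr, tp=tp, fp=fp, tn=tn, fn=fn,
                         threshold=threshold)


def _canon(pair) -> tuple:
    a, b = pair
    return (a, b) if str(a) <= str(b) else (b, a)


def sample_negatives(positives, universe, seed: int = 0,
                     n_samples: int | None = None) -> set:
    """Uniformly sample unordered non-interacting, non-self drug pairs.

    Negatives are drawn without replacement from all unordered pairs over
    ``universe`` that are not in ``positives``; by default as many as
    there are positives (balanced sampling).  Reproducible per seed.
    """
    pos = {_canon(p) for p in positives}
    drugs = sorted(universe, key=str)
    n = len(drugs)
    total_pairs = n * (n - 1) // 2
    n_candidates = total_pairs - len(pos)
    if n_samples is None:
        n_samples = len(pos)
    if n_samples > n_candidates:
        raise ValueError(
            f"cannot sample {n_samples} negatives: only {n_candidates} "
            f"candidate pairs exist (deficit {n_samples - n_candidates})")
    rng = np.random.default_rng(seed)
    if total_pairs <= 2_000_000:
        candidates = [p for p in itertools.combinations(drugs, 2)
                      if p not in pos]
        idx = rng.choice(len(candidates), size=n_samples, replace=False)
        return {candidates[i] for i in idx}
    # large universe: rejection sampling
    chosen: set = set()
    while len(chosen) < n_samples:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        p = _canon((drugs[i], drugs[j]))
        if p in pos or p in chosen:
            continue
        chosen.add(p)
    return chosen


def kfold_indices(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Shuffled partition of range(n) into k folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def summarize_reports(reports: list[MetricsReport]) -> dict:
    """Per-metric mean and standard deviation across folds."""
    out = {}
    for key in ("acc", "prec", "sen", "f1", "mcc", "auc", "aupr"):
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        out[key] = {"mean": float(np.nanmean(vals)),
                    "sd": float(np.nanstd(vals, ddof=1))
                    if len(vals) > 1 else 0.0}
    return out
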