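"""Presence-absence and presence-only validation statistics.

Self-contained implementations of the four statistics used to validate the
habitat-suitability models: ROC AUC (Mann-Whitney form), the true skill
statistic (TSS), Cohen's kappa at a threshold, and the continuous Boyce
index, plus the max-TSS threshold rule used to binarize continuous
suitability scores.

All binary metrics binarize with ``prediction = score >= threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lulc import ConfusionMatrix, kappa_coefficient


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given inputs (e.g. one class only)."""


@dataclass(frozen=True)
class EvalScores:
    """Per-model validation scores and the threshold used to binarize."""

    roc: float
    tss: float
    kappa: float
    boyce: float | None = None
    threshold_used: float = 0.5


def _check_binary(labels: np.ndarray) -> None:
    if labels.min() < 0 or labels.max() > 1:
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise UndefinedMetricError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    ranks = stats.rankdata(scores)  # average ranks handle ties
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    rank_sum = ranks[labels == 1].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _confusion_at(scores: np.ndarray, labels: np.ndarray, t: float):
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    return tp, fn, tn, fp


def tss_at_threshold(scores, labels, t: float) -> float:
    """Sensitivity + specificity - 1 (Youden's J) at threshold t."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    tp, fn, tn, fp = _confusion_at(scores, labels, t)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return float(sens + spec - 1.0)


def max_tss_threshold(scores, labels) -> tuple[float, float]:
    """Threshold maximizing TSS, scanned at midpoints of sorted unique scores.

    Candidates are the midpoints between consecutive unique scores plus the
    extremes just below/above all scores; the smallest maximizing threshold
    is returned on ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    uniq = np.unique(scores)
    candidates = [uniq[0] - 1.0]
    candidates.extend((uniq[:-1] + uniq[1:]) / 2.0)
    candidates.append(uniq[-1] + 1.0)
    best_t, best_tss = candidates[0], -np.inf
    for t in candidates:
        v = tss_at_threshold(scores, labels, t)
        if v > best_tss + 1e-15:
            best_t, best_tss = t, v
    return float(best_t), float(best_tss)


def cohen_kappa_at_threshold(scores, labels, t: float) -> float:
    """Cohen's kappa of the thresholded prediction against the labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    tp, fn, tn, fp = _confusion_at(scores, labels, t)
    cm = ConfusionMatrix(("absent", "present"), np.array([[tn, fp], [fn, tp]]))
    return kappa_coefficient(cm)


def boyce_index(
    presence_suit,
    background_suit,
    n_windows: int = 50,
    window_width: float = 0.02,
) -> float:
    """Continuous Boyce index.

    Suitability windows of the given width span [0, 1]; in each window the
    predicted-to-expected ratio P/E = (fraction of presences in the window)
    / (fraction of background in the window) is computed, and the index is
    the Spearman rank correlation between window midpoints and P/E.
    Windows with zero expected (background) fraction are skipped. A
    positive index means presences concentrate in high-suitability cells.

    The default (50 windows of width 0.02) partitions [0, 1] into disjoint
    narrow classes. Wider overlapping windows (the moving-window variant,
    e.g. ``n_windows=101, window_width=0.1``) smooth the P/E curve but
    correlate neighbouring windows, which widens the index's null
    distribution enough that a well-calibrated-but-uninformative model is
    no longer reliably scored near 0; the disjoint partition keeps the
    null concentrated while preserving the +-1 behaviour on monotone P/E.
    """
    pres = np.asarray(presence_suit, dtype=float)
    back = np.asarray(background_suit, dtype=float)
    if len(pres) == 0 or len(back) == 0:
        raise UndefinedMetricError("empty presence or background suitabilities")
    if n_windows < 2:
        raise UndefinedMetricError("need at least 2 windows")
    starts = np.linspace(0.0, 1.0 - window_width, n_windows)
    mids, ratios = [], []
    for lo in starts:
        hi = lo + window_width
        # right-closed on the final window so suitability 1.0 is counted
        if hi >= 1.0 - 1e-12:
            p = np.mean((pres >= lo) & (pres <= hi))
            e = np.mean((back >= lo) & (back <= hi))
        else:
            p = np.mean((pres >= lo) & (pres < hi))
            e = np.mean((back >= lo) & (back < hi))
        if e > 0:
            mids.append(lo + window_width / 2.0)
            ratios.append(p / e)
    if len(mids) < 2:
        raise UndefinedMetricError("fewer than 2 windows with nonzero expected fraction")
    rho = stats.spearmanr(mids, ratios).statistic
    if np.isnan(rho):  # constant P/E across windows
        return 0.0
    return float(rho)


def evaluate_at_max_tss(scores, labels) -> EvalScores:
    """ROC/TSS/kappa bundle with the max-TSS threshold (boyce left unset)."""
    t, tss = max_tss_threshold(scores, labels)
    return EvalScores(
        roc=roc_auc(scores, labels),
        tss=tss,
        kappa=cohen_kappa_at_threshold(scores, labels, t),
        boyce=None,
        threshold_used=t,
    )


def summarize_evaluation(report) -> "pd.DataFrame":
    """Unweighted mean and SE (sd/sqrt(n)) of each metric column over species.

    ``report`` is a DataFrame with one row per species and numeric metric
    columns (e.g. roc, tss, kappa, boyce).
    """
    import pandas as pd

    df = pd.DataFrame(report)
    if len(df) == 0:
        raise ValueError("empty evaluation report")
    num = df.select_dtypes("number")
    mean = num.mean()
    n = num.notna().sum()
    se = num.std(ddof=1).fillna(0.0) / np.sqrt(n)
    se = se.fillna(0.0)
    if len(df) == 1:
        se[:] = 0.0
    return pd.DataFrame({"mean": mean, "se": se})
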