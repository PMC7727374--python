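"""Probability calibration and evaluation on the Phred scale.

A MAPQ score encodes the misalignment probability p as
``Q = -10 * log10(p)``.  This module provides the classification
metrics used throughout the package (precision, recall, F1, Brier
score, average precision), a pool-adjacent-violators (PAVA) isotonic
regression used to calibrate raw classifier scores into probabilities,
the Phred conversions, assigned-vs-observed calibration curves, and the
per-read MAPQ recalibration step that maps every eligible alignment to
a new MAPQ via feature extraction -> scaling -> prediction ->
isotonic calibration -> Phred conversion.

The isotonic fit minimises sum_i w_i (y_i - yhat_i)^2 subject to
yhat_1 <= yhat_2 <= ... <= yhat_n over scores sorted ascending; PAVA
computes the exact global optimum.  Applying the model interpolates
linearly between breakpoints and clips outside their range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

__all__ = [
    "MetricsReport",
    "IsotonicModel",
    "precision_recall",
    "f1",
    "brier",
    "average_precision",
    "pava_fit",
    "pava_apply",
    "prob_to_mapq",
    "mapq_to_prob",
    "calibration_curve",
    "recalibrate",
    "metrics_report",
    "DEFAULT_MAPQ_CAP",
]

DEFAULT_MAPQ_CAP = 60


# ----------------------------------------------------------------------
# metrics

def precision_recall(tp: int, fp: int, fn: int) -> Tuple[float, float]:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN); zero denominators
    yield 0 (flagged with a warning)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        warnings.warn("precision undefined (TP + FP == 0); returning 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("recall undefined (TP + FN == 0); returning 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    return precision, recall


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def brier(f: Sequence[float], o: Sequence[int]) -> float:
    """Mean squared error between predicted probabilities and 0/1
    outcomes: (1/N) * sum (f_t - o_t)^2."""
    f = np.asarray(f, dtype=float)
    o = np.asarray(o, dtype=float)
    if f.shape != o.shape:
        raise ValueError("probabilities and outcomes differ in length")
    if f.size == 0:
        raise ValueError("need at least one prediction")
    return float(np.mean((f - o) ** 2))


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AP = sum_n (R_n - R_{n-1}) P_n over descending score thresholds."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("average precision undefined without positives")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    brier: Optional[float] = None
    average_precision: Optional[float] = None


def metrics_report(y_true: Sequence[int], y_pred: Sequence[int],
                   probabilities: Optional[Sequence[float]] = None,
                   scores: Optional[Sequence[float]] = None) -> MetricsReport:
    """Counts and metrics for binary misalignment predictions
    (positive class = 1 = misaligned)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r = precision_recall(tp, fp, fn)
    bs = brier(probabilities, y_true) if probabilities is not None else None
    rank = probabilities if probabilities is not None else scores
    ap = average_precision(rank, y_true) if rank is not None and y_true.sum() else None
    return MetricsReport(tp, fp, fn, tn, p, r, f1(p, r), bs, ap)


# ----------------------------------------------------------------------
# isotonic regression (pool-adjacent-violators)

@dataclass
class IsotonicModel:
    """Breakpoints ``x`` (sorted, unique) with fitted non-decreasing
    values ``y`` and the pooled weights used in fitting."""

    x: np.ndarray
    y: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.y) < -1e-12):
            raise ValueError("fitted values must be non-decreasing")


def pava_fit(scores: Sequence[float], outcomes: Sequence[float],
             weights: Optional[Sequence[float]] = None) -> IsotonicModel:
    """Weighted least-squares non-decreasing fit of outcomes against
    sorted scores, solved exactly by pool-adjacent-violators.

    Tied scores are pre-pooled to their weighted mean so the solution
    does not depend on sort stability.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if s.size != y.size:
        raise ValueError("scores and outcomes differ in length")
    if s.size < 2:
        raise ValueError("need at least 2 points")
    if weights is None:
        w = np.ones_like(s)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    order = np.argsort(s, kind="stable")
    s, y, w = s[order], y[order], w[order]
    # pre-pool ties by weighted mean
    ux, first = np.unique(s, return_index=True)
    if ux.size < s.size:
        wy = np.add.reduceat(w * y, first)
        ww = np.add.reduceat(w, first)
        s, y, w = ux, wy / ww, ww
    # PAVA with a block stack
    vals: List[float] = []
    wts: List[float] = []
    sizes: List[int] = []
    for yi, wi in zip(y, w):
        vals.append(yi)
        wts.append(wi)
        sizes.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2, n2 = vals.pop(), wts.pop(), sizes.pop()
            v1, w1, n1 = vals.pop(), wts.pop(), sizes.pop()
            vals.append((v1 * w1 + v2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
            sizes.append(n1 + n2)
    fitted = np.repeat(vals, sizes)
    return IsotonicModel(x=s, y=fitted, w=w)


def pava_apply(model: IsotonicModel, scores: Sequence[float]) -> np.ndarray:
    """Evaluate the isotonic fit with linear interpolation between
    breakpoints; inputs outside the range clip to the end values."""
    s = np.asarray(scores, dtype=float)
    return np.interp(s, model.x, model.y)


# ----------------------------------------------------------------------
# Phred conversions

def prob_to_mapq(p: float, cap: int = DEFAULT_MAPQ_CAP) -> int:
    """Q = round(-10 * log10(p)), capped; p = 0 maps to the cap."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability out of [0, 1]: {p}")
    if p == 0.0:
        return cap
    return min(cap, int(round(-10.0 * math.log10(p))))


def mapq_to_prob(q: float) -> float:
    """p = 10^(-Q/10)."""
    if q < 0:
        raise ValueError("MAPQ must be >= 0")
    return 10.0 ** (-q / 10.0)


# ----------------------------------------------------------------------
# calibration curves

def calibration_curve(assigned_mapq: Sequence[int], labels: Sequence[int],
                      cap: int = DEFAULT_MAPQ_CAP) -> pd.DataFrame:
    """Assigned vs observed MAPQ.

    For each distinct assigned score, the observed score is the
    misaligned fraction of its reads pushed through the Phred formula
    (groups with no misaligned reads map to the cap).  Perfectly
    calibrated scores lie on the diagonal.
    """
    q = np.asarray(assigned_mapq)
    lab = np.asarray(labels)
    rows = []
    for val in np.unique(q):
        mask = q == val
        n = int(mask.sum())
        frac = lab[mask].mean()
        rows.append({"ASSIGNED_Q": int(val),
                     "OBSERVED_Q": prob_to_mapq(float(frac), cap=cap),
                     "N": n})
    return pd.DataFrame(rows, columns=["ASSIGNED_Q", "OBSERVED_Q", "N"])


def curve_mean_abs_error(curve: pd.DataFrame) -> float:
    """Mean |assigned - observed| over the curve's rows."""
    return float(np.abs(curve["ASSIGNED_Q"] - curve["OBSERVED_Q"]).mean())


def plot_calibration_curves(curves: Dict[str, pd.DataFrame], path: str,
                            cap: int = DEFAULT_MAPQ_CAP) -> None:
    """Assigned-vs-observed MAPQ scatter for one or more score sets
    (e.g. {"original": ..., "recalibrated": ...}); perfectly calibrated
    scores fall on the diagonal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, cap], [0, cap], "k--", lw=1, label="perfect calibration")
    for name, curve in curves.items():
        ax.scatter(curve["ASSIGNED_Q"], curve["OBSERVED_Q"],
                   s=12 + 2 * np.log1p(curve["N"]), alpha=0.7, label=name)
    ax.set_xlabel("assigned MAPQ")
    ax.set_ylabel("observed MAPQ")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ----------------------------------------------------------------------
# per-read recalibration

def recalibrate(model, records, reference: Dict[str, str],
                cap: int = DEFAULT_MAPQ_CAP,
                lowq_threshold: Optional[int] = None,
                ) -> Tuple[Dict[Tuple[str, int], int], pd.DataFrame]:
    """New MAPQ for every primary, mapped, non-multi-mapped read.

    ``model`` is a fitted :class:`~mapqcal.models.TrainedModel`; reads
    it cannot score (multi-mapped, unmapped, missing tags) keep their
    original MAPQ and are absent from the returned mapping.  Returns
    ``(read-key -> new MAPQ, CalibratedRead table)`` with columns
    READ_KEY, P_MISALIGN, MAPQ_OLD, MAPQ_NEW.
    """
    from . import features as F

    if not model.produces_probabilities and model.calibrator is None:
        raise ValueError("model without probability output needs a calibrator")
    kwargs = {}
    if lowq_threshold is not None:
        kwargs["lowq_threshold"] = lowq_threshold
    table = F.feature_table(records, reference, labels={}, **kwargs)
    if len(table) == 0:
        return {}, pd.DataFrame(
            columns=["READ_KEY", "P_MISALIGN", "MAPQ_OLD", "MAPQ_NEW"])
    X = table[F.FEATURE_NAMES]
    p = model.predict_calibrated(X)
    old_q = table["MAPPING_QUALITY"].to_numpy().astype(int)
    new_q = np.array([prob_to_mapq(float(pi), cap=cap) for pi in p])
    mapping: Dict[Tuple[str, int], int] = {}
    for key_str, q in zip(table["READ_KEY"], new_q):
        name, mate = key_str.rsplit("/", 1)
        mapping[(name, int(mate))] = int(q)
    out = pd.DataFrame({
        "READ_KEY": table["READ_KEY"],
        "P_MISALIGN": p,
        "MAPQ_OLD": old_q,
        "MAPQ_NEW": new_q,
    })
    return mapping, out
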