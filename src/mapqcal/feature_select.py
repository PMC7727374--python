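"""Feature ranking by Information Gain and ReliefF.

Ranking runs on a *balanced selection set*: every misaligned (class 1)
read plus an equal-count random sample of correctly aligned reads.
Information Gain discretises continuous features into equal-frequency
bins; ReliefF scores features by how well they separate each sampled
instance from its nearest misses relative to its nearest hits.  The
final selection is configuration-driven (top-k by Information Gain,
default 7); the largest score gap is reported but not trusted
automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import entropy

__all__ = [
    "balanced_selection_set",
    "info_gain",
    "relieff",
    "rank_and_cut",
    "FeatureRanking",
]


def balanced_selection_set(matrix: pd.DataFrame, labels: np.ndarray,
                           seed: int = 0) -> Tuple[pd.DataFrame, np.ndarray]:
    """All class-1 rows plus an equal-count random class-0 sample."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    if neg.size < pos.size:
        raise ValueError("class 0 smaller than class 1; cannot balance")
    rng = np.random.Generator(np.random.PCG64(seed))
    chosen_neg = rng.choice(neg, size=pos.size, replace=False)
    idx = np.concatenate([pos, chosen_neg])
    idx.sort()
    return matrix.iloc[idx].reset_index(drop=True), labels[idx]


def _discretise(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin codes; low-cardinality columns are used as-is."""
    uniq = np.unique(column)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, column)
    ranks = pd.qcut(column, n_bins, labels=False, duplicates="drop")
    return np.asarray(ranks)


def info_gain(feature_column: np.ndarray, labels: np.ndarray,
              n_bins: int = 10) -> float:
    """H(labels) - H(labels | binned feature), in bits."""
    labels = np.asarray(labels)
    column = np.asarray(feature_column, dtype=float)
    if labels.size < 2:
        raise ValueError("need at least 2 rows")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        return 0.0
    h_y = entropy(counts, base=2)
    bins = _discretise(column, n_bins)
    h_cond = 0.0
    n = labels.size
    for b in np.unique(bins):
        mask = bins == b
        _, c = np.unique(labels[mask], return_counts=True)
        h_cond += (mask.sum() / n) * entropy(c, base=2)
    return float(max(0.0, h_y - h_cond))


def relieff(matrix: np.ndarray, labels: np.ndarray, k_neighbors: int = 10,
            n_sample: Optional[int] = None, seed: int = 0) -> np.ndarray:
    """Per-feature ReliefF weights (features must be scaled to [0, 1]).

    For each sampled instance the weight of a feature decreases by its
    mean distance to the k nearest *hits* (same class) and increases by
    the prior-weighted mean distance to the k nearest *misses* (other
    classes).  Higher weight = more informative.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    n, n_feat = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    min_class = counts.min()
    if min_class - 1 < k_neighbors:
        warnings.warn(f"reducing k from {k_neighbors} to {min_class - 1}")
        k_neighbors = max(1, min_class - 1)
    rng = np.random.Generator(np.random.PCG64(seed))
    if n_sample is None or n_sample >= n:
        sample_idx = np.arange(n)
    else:
        sample_idx = rng.choice(n, size=n_sample, replace=False)
    W = np.zeros(n_feat)
    m = sample_idx.size
    for i in sample_idx:
        diffs = np.abs(X - X[i])           # (n, n_feat), already range-normalised
        dist = diffs.sum(axis=1)
        dist[i] = np.inf
        same = y == y[i]
        hit_idx = np.flatnonzero(same)
        hit_idx = hit_idx[np.argsort(dist[hit_idx])][:k_neighbors]
        W -= diffs[hit_idx].mean(axis=0) / m
        for c in classes:
            if c == y[i]:
                continue
            miss_idx = np.flatnonzero(y == c)
            miss_idx = miss_idx[np.argsort(dist[miss_idx])][:k_neighbors]
            w_c = priors[c] / (1.0 - priors[y[i]])
            W += w_c * diffs[miss_idx].mean(axis=0) / m
    return W


@dataclass
class FeatureRanking:
    table: pd.DataFrame          # FEATURE, INFO_GAIN, RELIEFF, RANK
    selected: List[str]          # top-k by Info Gain
    largest_gap_after: int       # 1-based rank preceding the largest IG drop

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def rank_and_cut(ig_scores: Dict[str, float], relieff_scores: Dict[str, float],
                 k_keep: int = 7) -> FeatureRanking:
    """Order features by Information Gain (descending, name tie-break)
    and return the top ``k_keep`` plus the full ranking and the position
    of the largest consecutive Info-Gain drop."""
    if set(ig_scores) != set(relieff_scores):
        raise ValueError("score maps must cover the same features")
    if k_keep > len(ig_scores):
        raise ValueError("k_keep exceeds feature count")
    ordered = sorted(ig_scores, key=lambda f: (-ig_scores[f], f))
    ig = np.array([ig_scores[f] for f in ordered])
    gaps = ig[:-1] - ig[1:]
    largest_gap_after = int(np.argmax(gaps)) + 1 if gaps.size else 0
    table = pd.DataFrame({
        "FEATURE": ordered,
        "INFO_GAIN": ig,
        "RELIEFF": [relieff_scores[f] for f in ordered],
        "RANK": np.arange(1, len(ordered) + 1),
    })
    return FeatureRanking(table=table, selected=ordered[:k_keep],
                          largest_gap_after=largest_gap_after)
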