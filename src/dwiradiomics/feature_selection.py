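"""The three univariate/greedy feature-selection criteria.

Each criterion ranks candidate features of a binary task and returns the ten
(by default) with the highest discriminatory potential:

* Fisher — ratio of between-class to within-class variance.
* POE + ACC — greedy minimization of the probability of classification error
  of the best single-threshold classifier, penalized by the average absolute
  Pearson correlation with already-selected features (Mucciardi-Gose).
* MI — mutual information (nats) between the class label and the feature
  discretized into equal-frequency bins.

Candidate features must be complete (no missing values) and non-constant;
excluded features are recorded with their reason.  All ties are broken by
canonical catalogue order so selection is fully deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import TaskError
from .io_formats import FeatureTable

FISHER = "FISHER"
POE_ACC = "POE_ACC"
MI = "MI"
CRITERIA = (FISHER, POE_ACC, MI)

DEFAULT_K = 10
DEFAULT_MI_BINS = 8


@dataclass
class SelectedFeatureSet:
    """Ordered result of one selection criterion on one binary task."""

    criterion: str
    names: list[str]
    scores: list[float]
    excluded: dict[str, str] = field(default_factory=dict)


def _check_binary(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    if classes.size != 2:
        raise TaskError(f"selection requires exactly 2 classes, got {classes.size}")
    return labels == classes[0], labels == classes[1]


def fisher_coefficient(values: np.ndarray, labels: np.ndarray) -> float:
    """Between-class over within-class variance (population variances).

    Perfect separation (zero within-class variance with distinct means)
    returns +inf, ranked above every finite score; a fully degenerate feature
    returns 0.
    """
    values = np.asarray(values, dtype=float)
    in_a, in_b = _check_binary(np.asarray(labels))
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise TaskError("each class needs at least 2 lesions")
    n = values.size
    m = values.mean()
    var_between = 0.0
    var_within = 0.0
    for cls in (in_a, in_b):
        v = values[cls]
        var_between += v.size * (v.mean() - m) ** 2 / n
        var_within += v.size * v.var() / n
    if var_within == 0.0:
        return math.inf if var_between > 0 else 0.0
    return var_between / var_within


def poe_single(values: np.ndarray, labels: np.ndarray) -> float:
    """Probability of error of the best single-threshold classifier.

    Thresholds are placed midway between consecutive sorted unique values and
    both polarities are scanned; the minimum misclassification fraction is
    returned (at most 0.5 because the polarities are complementary).
    """
    values = np.asarray(values, dtype=float)
    in_a, _ = _check_binary(np.asarray(labels))
    order = np.argsort(values, kind="stable")
    v_sorted = values[order]
    a_sorted = in_a[order].astype(int)
    n = values.size
    n_a = int(in_a.sum())
    # after position i (0..n): count of class-A values <= threshold i
    cum_a = np.concatenate([[0], np.cumsum(a_sorted)])
    # candidate split positions: between distinct consecutive values
    distinct = np.nonzero(np.diff(v_sorted) > 0)[0] + 1  # split before index
    if distinct.size == 0:
        return 0.5  # constant feature: no threshold, either polarity errs half
    best = n  # in error counts
    for pos in distinct:
        a_left = cum_a[pos]
        b_left = pos - a_left
        # polarity 1: left -> class A, right -> class B
        err1 = b_left + (n_a - a_left)
        err2 = n - err1  # opposite polarity
        best = min(best, err1, err2)
    return best / n


def mutual_information(values: np.ndarray, labels: np.ndarray, n_bins: int = DEFAULT_MI_BINS) -> float:
    """MI (nats) between the label and the equal-frequency-binned feature.

    Duplicate quantile edges are merged; a constant feature has MI 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    in_a, _ = _check_binary(np.asarray(labels))
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)))
    if edges.size <= 2:
        return 0.0
    inner = edges[1:-1]
    bins = np.searchsorted(inner, values, side="right")
    n = values.size
    n_bins_eff = int(bins.max()) + 1
    joint = np.zeros((n_bins_eff, 2))
    np.add.at(joint, (bins, (~in_a).astype(int)), 1.0)
    joint /= n
    pb = joint.sum(axis=1, keepdims=True)
    pc = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(joint > 0, joint / (pb * pc), 1.0)
        mi = float(np.sum(np.where(joint > 0, joint * np.log(ratio), 0.0)))
    return max(mi, 0.0)


def candidate_features(table: FeatureTable) -> tuple[list[str], dict[str, str]]:
    """Split features into candidates and excluded (missing or constant)."""
    X = table.matrix
    names = table.feature_names
    candidates, excluded = [], {}
    for j, name in enumerate(names):
        col = X[:, j]
        if np.any(~np.isfinite(col)):
            excluded[name] = "missing values"
        elif np.all(col == col[0]):
            excluded[name] = "zero variance"
        else:
            candidates.append(name)
    return candidates, excluded


def _top_k(names: list[str], scores: np.ndarray, k: int) -> tuple[list[str], list[float]]:
    """Top-k by descending score; ties broken by canonical (input) order."""
    idx = np.lexsort((np.arange(len(names)), -scores))[:k]
    return [names[i] for i in idx], [float(scores[i]) for i in idx]


def _select_univariate(table, criterion, score_fn, k):
    candidates, excluded = candidate_features(table)
    if len(candidates) == 0:
        raise TaskError("no candidate features")
    if len(candidates) < k:
        warnings.warn(
            f"only {len(candidates)} candidate features for k={k}; returning all",
            stacklevel=3,
        )
        k = len(candidates)
    cols = {n: j for j, n in enumerate(table.feature_names)}
    X = table.matrix
    y = table.labels
    scores = np.array([score_fn(X[:, cols[n]], y) for n in candidates])
    names, vals = _top_k(candidates, scores, k)
    return SelectedFeatureSet(criterion=criterion, names=names, scores=vals, excluded=excluded)


def select_fisher(table: FeatureTable, k: int = DEFAULT_K) -> SelectedFeatureSet:
    """Top-k features by Fisher coefficient."""
    return _select_univariate(table, FISHER, fisher_coefficient, k)


def select_mi(table: FeatureTable, k: int = DEFAULT_K, n_bins: int = DEFAULT_MI_BINS) -> SelectedFeatureSet:
    """Top-k features by mutual information with the label."""
    return _select_univariate(table, MI, lambda v, y: mutual_information(v, y, n_bins), k)


def select_poe_acc(table: FeatureTable, k: int = DEFAULT_K) -> SelectedFeatureSet:
    """Greedy POE + ACC selection.

    The first feature minimizes POE; feature j+1 minimizes
    POE(f) + (1/j) * sum_{s in selected} |pearson r(f, s)|.  Raw feature
    values are used throughout; ties go to canonical order.
    """
    candidates, excluded = candidate_features(table)
    if len(candidates) == 0:
        raise TaskError("no candidate features")
    if len(candidates) < k:
        warnings.warn(
            f"only {len(candidates)} candidate features for k={k}; returning all",
            stacklevel=2,
        )
        k = len(candidates)
    cols = {n: j for j, n in enumerate(table.feature_names)}
    X = table.matrix
    y = table.labels
    V = np.stack([X[:, cols[n]] for n in candidates], axis=1)
    poe = np.array([poe_single(V[:, j], y) for j in range(V.shape[1])])
    # standardized columns for fast Pearson correlations
    Z = (V - V.mean(axis=0)) / V.std(axis=0)
    n = V.shape[0]

    remaining = list(range(len(candidates)))
    chosen: list[int] = []
    scores: list[float] = []
    corr_sum = np.zeros(len(candidates))
    while len(chosen) < k:
        if chosen:
            cost = poe + corr_sum / len(chosen)
        else:
            cost = poe.copy()
        rem = np.array(remaining)
        best_pos = rem[np.lexsort((rem, cost[rem]))[0]]
        chosen.append(int(best_pos))
        scores.append(float(cost[best_pos]))
        remaining.remove(int(best_pos))
        corr_sum += np.abs(Z.T @ Z[:, best_pos]) / n
    return SelectedFeatureSet(
        criterion=POE_ACC,
        names=[candidates[j] for j in chosen],
        scores=scores,
        excluded=excluded,
    )


def select_features(table: FeatureTable, criterion: str, k: int = DEFAULT_K, mi_bins: int = DEFAULT_MI_BINS) -> SelectedFeatureSet:
    """Dispatch to one of the three criteria by name."""
    if criterion == FISHER:
        return select_fisher(table, k)
    if criterion == POE_ACC:
        return select_poe_acc(table, k)
    if criterion == MI:
        return select_mi(table, k, mi_bins)
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
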