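"""LDA reduction to most-discriminatory features and k-NN LOOCV classification.

For each binary task and each selection criterion the selected (at most ten)
features are z-scored, projected onto the Fisher discriminant axis (the MDF
coordinate), and classified by k-nearest neighbours under leave-one-out
cross-validation.  Two evaluation protocols are provided:

* ``FULL`` — selection and LDA are fitted once on the full task data and
  LOOCV wraps only the k-NN vote.  This is the literal historical protocol
  and is optimistic for small samples.
* ``NESTED`` — selection and LDA are refitted inside every LOOCV fold, so the
  held-out lesion never influences the projection it is judged by.

Every distance and vote tie is broken deterministically (lower lesion index;
larger class, then lower label order), so a fixed table and configuration
yield a bit-identical report.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ConfigError, TaskError
from .feature_selection import CRITERIA, DEFAULT_K, DEFAULT_MI_BINS, select_features
from .io_formats import FeatureTable

FULL = "FULL"
NESTED = "NESTED"

#: LDA within-class scatter shrinkage applied when the scatter is singular.
LDA_SHRINKAGE = 1e-3

#: Accuracy (percent) above which a task is flagged as clinically relevant.
CLINICAL_THRESHOLD = 80.0


@dataclass(frozen=True)
class ClassifierConfig:
    """k-NN and protocol settings: k must be odd, mode FULL or NESTED."""

    k: int = 1
    mode: str = FULL
    selection_k: int = DEFAULT_K
    mi_bins: int = DEFAULT_MI_BINS

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ConfigError(f"k must be an odd positive integer, got {self.k}")
        if self.mode not in (FULL, NESTED):
            raise ConfigError(f"mode must be {FULL} or {NESTED}, got {self.mode!r}")


@dataclass
class MdfProjection:
    """A fitted 1-D Fisher discriminant: z-scoring parameters and weights.

    The sign convention puts the second task class at the higher projected
    mean.
    """

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    shrinkage_used: bool = False

    def project(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.means) / self.sds
        return Z @ self.weights


def fit_lda(X: np.ndarray, y: np.ndarray, class_order: tuple) -> MdfProjection:
    """Fit the Fisher discriminant w = S_w^-1 (m1 - m0) on z-scored features.

    ``class_order`` fixes which label sits at the higher projected mean (the
    second).  A singular pooled scatter gets diagonal shrinkage
    S_w + lambda*tr(S_w)/p*I and, failing that, a minimum-norm pseudo-inverse.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    in0 = y == class_order[0]
    in1 = y == class_order[1]
    if in0.sum() < 2 or in1.sum() < 2:
        raise TaskError("each class needs at least 2 lesions to fit the LDA")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    Z = (X - means) / sds
    m0 = Z[in0].mean(axis=0)
    m1 = Z[in1].mean(axis=0)
    n = Z.shape[0]
    Sw = np.zeros((Z.shape[1], Z.shape[1]))
    for sel, m in ((in0, m0), (in1, m1)):
        D = Z[sel] - m
        Sw += D.T @ D
    Sw /= n
    diff = m1 - m0
    shrunk = False
    try:
        cond = np.linalg.cond(Sw)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e10:
        Sw = Sw + LDA_SHRINKAGE * np.trace(Sw) / Sw.shape[0] * np.eye(Sw.shape[0])
        shrunk = True
    try:
        w = np.linalg.solve(Sw, diff)
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(Sw) @ diff
        shrunk = True
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    if float(w @ diff) < 0:  # enforce the sign convention
        w = -w
    return MdfProjection(
        feature_names=[], means=means, sds=sds, weights=w, shrinkage_used=shrunk
    )


def _vote(neigh_labels: np.ndarray, class_order: tuple, class_sizes: dict) -> object:
    counts = {c: int(np.sum(neigh_labels == c)) for c in class_order}
    c0, c1 = class_order
    if counts[c0] > counts[c1]:
        return c0
    if counts[c1] > counts[c0]:
        return c1
    # even split: prefer the larger class, then the lower label order
    if class_sizes[c0] != class_sizes[c1]:
        return c0 if class_sizes[c0] > class_sizes[c1] else c1
    return c0


def knn_loocv(coords: np.ndarray, y: np.ndarray, class_order: tuple, config: ClassifierConfig) -> dict:
    """Leave-one-out k-NN on (1-D) MDF coordinates with deterministic ties.

    Returns confusion counts, error count and misclassification percentage.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float).T).T
    if coords.ndim == 1:
        coords = coords[:, None]
    y = np.asarray(y)
    n = coords.shape[0]
    if n < 3:
        raise TaskError("LOOCV needs at least 3 lesions")
    if config.k >= n:
        raise ConfigError(f"k={config.k} must be smaller than n={n}")
    class_sizes = {c: int(np.sum(y == c)) for c in class_order}
    predictions = []
    for i in range(n):
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        order = np.lexsort((np.arange(n), d))
        order = order[order != i][: config.k]
        predictions.append(_vote(y[order], class_order, class_sizes))
    predictions = np.array(predictions, dtype=object)
    confusion = {
        f"{true}->{pred}": int(np.sum((y == true) & (predictions == pred)))
        for true in class_order
        for pred in class_order
    }
    errors = int(np.sum(predictions != y))
    return {
        "n": n,
        "confusion": confusion,
        "errors": errors,
        "misclassification_pct": 100.0 * errors / n,
        "accuracy_pct": 100.0 * (1.0 - errors / n),
    }


def _knn_predict_one(train_coords: np.ndarray, train_y: np.ndarray, test_coord: float, class_order: tuple, k: int) -> object:
    d = np.abs(train_coords - test_coord)
    order = np.lexsort((np.arange(train_coords.size), d))[:k]
    class_sizes = {c: int(np.sum(train_y == c)) for c in class_order}
    return _vote(train_y[order], class_order, class_sizes)


def _binary_view(table: FeatureTable, task: tuple) -> tuple[FeatureTable, np.ndarray, tuple]:
    """Restrict a table to a task; one-vs-rest pools every other label.

    Returns (subtable, binary labels, class order).  The class order is
    (first group, second group) as given in the task.
    """
    labels = table.labels
    group_a, group_b = task
    if isinstance(group_a, str):
        group_a = (group_a,)
    is_rest = group_b == "rest"
    if is_rest:
        group_b = tuple(sorted(set(labels) - set(group_a)))
    elif isinstance(group_b, str):
        group_b = (group_b,)
    name_a = "+".join(group_a)
    name_b = "rest" if is_rest else "+".join(group_b)
    in_a = np.isin(labels, group_a)
    in_b = np.isin(labels, group_b)
    if not in_a.any() or not in_b.any():
        raise TaskError(f"task {task}: a group is empty")
    sub = table.subset(in_a | in_b)
    y = np.where(np.isin(sub.labels, group_a), name_a, name_b)
    return sub, y, (name_a, name_b)


def _relabel(sub: FeatureTable, y: np.ndarray) -> FeatureTable:
    data = sub.data.copy()
    data["class_label"] = y
    return FeatureTable(data)


def run_task(table: FeatureTable, task: tuple, config: ClassifierConfig = ClassifierConfig()) -> dict:
    """Evaluate one binary task with all three selection criteria.

    Returns a report entry with per-criterion accuracy and the best criterion
    (ties resolved in the order FISHER, POE_ACC, MI).
    """
    sub, y, class_order = _binary_view(table, task)
    n0 = int(np.sum(y == class_order[0]))
    n1 = int(np.sum(y == class_order[1]))
    if n0 < 2 or n1 < 2:
        raise TaskError(f"task {task}: each group needs >= 2 lesions (got {n0}, {n1})")
    btable = _relabel(sub, y)
    per_criterion = {}
    for criterion in CRITERIA:
        if config.mode == FULL:
            per_criterion[criterion] = _run_full(btable, class_order, criterion, config)
        else:
            per_criterion[criterion] = _run_nested(btable, class_order, criterion, config)
    best = max(
        CRITERIA,
        key=lambda c: (per_criterion[c]["accuracy_pct"], -CRITERIA.index(c)),
    )
    return {
        "task": [class_order[0], class_order[1]],
        "n": n0 + n1,
        "group_sizes": {class_order[0]: n0, class_order[1]: n1},
        "criteria": per_criterion,
        "best_criterion": best,
        "best_accuracy_pct": per_criterion[best]["accuracy_pct"],
    }


def _run_full(btable: FeatureTable, class_order: tuple, criterion: str, config: ClassifierConfig) -> dict:
    selected = select_features(btable, criterion, config.selection_k, config.mi_bins)
    cols = [btable.feature_names.index(n) for n in selected.names]
    X = btable.matrix[:, cols]
    y = btable.labels
    proj = fit_lda(X, y, class_order)
    proj.feature_names = list(selected.names)
    coords = proj.project(X)
    result = knn_loocv(coords, y, class_order, config)
    result["selected_features"] = list(selected.names)
    result["selection_scores"] = list(selected.scores)
    result["shrinkage_used"] = proj.shrinkage_used
    return result


def _run_nested(btable: FeatureTable, class_order: tuple, criterion: str, config: ClassifierConfig) -> dict:
    y = btable.labels
    n = len(btable)
    if config.k >= n:
        raise ConfigError(f"k={config.k} must be smaller than n={n}")
    all_names = btable.feature_names
    X_all = btable.matrix
    predictions = []
    fold_features: list[list[str]] = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        train = btable.subset(keep)
        if int(np.sum(train.labels == class_order[0])) < 2 or int(
            np.sum(train.labels == class_order[1])
        ) < 2:
            raise TaskError("a training fold lost a class; group too small for NESTED mode")
        selected = select_features(train, criterion, config.selection_k, config.mi_bins)
        cols = [all_names.index(nm) for nm in selected.names]
        proj = fit_lda(X_all[keep][:, cols], y[keep], class_order)
        train_coords = proj.project(X_all[keep][:, cols])
        test_coord = float(proj.project(X_all[i : i + 1, cols])[0])
        predictions.append(
            _knn_predict_one(train_coords, y[keep], test_coord, class_order, config.k)
        )
        fold_features.append(list(selected.names))
    predictions = np.array(predictions, dtype=object)
    confusion = {
        f"{true}->{pred}": int(np.sum((y == true) & (predictions == pred)))
        for true in class_order
        for pred in class_order
    }
    errors = int(np.sum(predictions != y))
    counts: dict[str, int] = {}
    for names in fold_features:
        for nm in names:
            counts[nm] = counts.get(nm, 0) + 1
    stable = sorted(counts, key=lambda nm: (-counts[nm], all_names.index(nm)))[: config.selection_k]
    return {
        "n": n,
        "confusion": confusion,
        "errors": errors,
        "misclassification_pct": 100.0 * errors / n,
        "accuracy_pct": 100.0 * (1.0 - errors / n),
        "selected_features": stable,
        "selection_scores": [counts[nm] / n for nm in stable],
        "shrinkage_used": False,
    }


def run_all_tasks(
    table: FeatureTable,
    classes: tuple[str, ...] | None = None,
    config: ClassifierConfig = ClassifierConfig(),
    contrasts: dict[str, tuple[str, ...]] | None = None,
    clinical_threshold: float = CLINICAL_THRESHOLD,
) -> dict:
    """Enumerate all pairwise, one-vs-rest and declared contrast tasks.

    Produces the symmetric accuracy grid with the best criterion per cell;
    cells whose groups are too small are marked not computable.  Accuracies at
    or above ``clinical_threshold`` percent are flagged.
    """
    if classes is None:
        classes = tuple(dict.fromkeys(table.labels))
    if len(classes) < 2:
        raise TaskError("need at least 2 classes")
    tasks: list[tuple] = [(a, b) for a, b in combinations(classes, 2)]
    tasks += [(c, "rest") for c in classes]
    for name, group in (contrasts or {}).items():
        tasks.append((tuple(group), "rest"))
    cells = []
    for task in tasks:
        try:
            entry = run_task(table, task, config)
            entry["computable"] = True
            entry["clinically_relevant"] = bool(
                entry["best_accuracy_pct"] >= clinical_threshold
            )
        except (TaskError, ConfigError) as exc:
            a, b = task
            name_a = a if isinstance(a, str) else "+".join(a)
            entry = {
                "task": [name_a, b if isinstance(b, str) else "+".join(b)],
                "computable": False,
                "reason": str(exc),
            }
        cells.append(entry)
    return {
        "classes": list(classes),
        "mode": config.mode,
        "k": config.k,
        "clinical_threshold_pct": clinical_threshold,
        "cells": cells,
    }


def grid_lookup(report: dict, group_a: str, group_b: str) -> dict | None:
    """Fetch a grid cell by its two group names, order-insensitively."""
    want = {group_a, group_b}
    for cell in report["cells"]:
        if set(cell["task"]) == want:
            return cell
    return None
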