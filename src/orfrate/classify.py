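"""Nearest-neighbor classification, jackknife evaluation and IFS.

A query ORF is assigned the class of the training ORF minimizing the cosine
distance

    d(x, y) = 1 - <x, y> / (|x| |y|)

Jackknife (leave-one-out) accuracy holds each sample out in turn, builds the
predictor from the remainder, and aggregates correct counts per class.
Within every fold, missing feature values are imputed with the training-fold
feature mean and, by default, each feature is min-max scaled to [0, 1] using
training-fold extremes (raw scales such as CDS length would otherwise
dominate the inner product); ``scale="none"`` evaluates raw vectors.

Incremental feature selection (IFS) walks a ranked feature list, evaluating
jackknife accuracy on the first k features for k = 1..k_max; the subset at
the accuracy peak (ties to the smallest k) is the optimal feature set.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import (
    EvalResult,
    FeatureMatrix,
    HIGH,
    IfsCurve,
    LabelVector,
    LOW,
    RankedFeatures,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - cosine similarity; in [0, 2].  A zero vector gives the maximal 2.0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        logger.warning("cosine distance of a zero vector defined as 2.0")
        return 2.0
    return float(1.0 - np.dot(x, y) / (nx * ny))


def nna_predict(
    train: np.ndarray, train_labels: np.ndarray, query: np.ndarray
) -> str:
    """Label of the nearest training row; distance ties go to the earliest row."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] == 0:
        raise ValidationError("training set must be a nonempty 2-D array")
    query = np.asarray(query, dtype=float)
    if query.shape != (train.shape[1],):
        raise ValidationError("query dimension does not match training set")
    distances = _cosine_distances(train, query)
    return str(train_labels[int(np.argmin(distances))])


def _cosine_distances(train: np.ndarray, query: np.ndarray) -> np.ndarray:
    qn = np.linalg.norm(query)
    tn = np.linalg.norm(train, axis=1)
    out = np.full(train.shape[0], 2.0)
    if qn == 0.0:
        return out
    ok = tn > 0
    out[ok] = 1.0 - (train[ok] @ query) / (tn[ok] * qn)
    return out


def jackknife_accuracy(
    matrix: FeatureMatrix,
    labels: LabelVector,
    feature_subset: list[str] | None = None,
    scale: str = "minmax",
) -> EvalResult:
    """Leave-one-out accuracy of the nearest-neighbor rule on a feature subset."""
    if scale not in ("minmax", "none"):
        raise ValidationError(f"unknown scaling mode {scale!r}")
    sub = matrix if feature_subset is None else matrix.subset(feature_subset)
    n = sub.n_samples
    if n < 2:
        raise ValidationError("jackknife needs at least 2 samples")
    if len(labels) != n:
        raise ValidationError("label length does not match sample count")
    labels.require_both_classes()

    X = sub.values
    miss = sub.missing_mask
    X0 = np.where(miss, 0.0, X)
    obs = ~miss
    col_sum = X0.sum(axis=0)
    col_count = obs.sum(axis=0)

    y = labels.labels
    correct_high = correct_low = 0
    idx = np.arange(n)
    for i in range(n):
        train_rows = idx != i
        count = col_count - obs[i]
        mean = np.divide(
            col_sum - X0[i],
            count,
            out=np.zeros_like(col_sum),
            where=count > 0,
        )
        Xtr = X0[train_rows] + miss[train_rows] * mean
        xq = np.where(miss[i], mean, X0[i])
        if scale == "minmax":
            lo = Xtr.min(axis=0)
            span = Xtr.max(axis=0) - lo
            span[span == 0] = 1.0
            Xtr = (Xtr - lo) / span
            xq = (xq - lo) / span
        pred = y[train_rows][int(np.argmin(_cosine_distances(Xtr, xq)))]
        if pred == y[i]:
            if y[i] == HIGH:
                correct_high += 1
            else:
                correct_low += 1
    return EvalResult(
        correct_high=correct_high,
        correct_low=correct_low,
        n_high=labels.n_high,
        n_low=labels.n_low,
    )


def ifs(
    matrix: FeatureMatrix,
    labels: LabelVector,
    ranking: RankedFeatures,
    k_max: int | None = None,
    scale: str = "minmax",
) -> IfsCurve:
    """Evaluate nested prefixes of a ranked feature list (k = 1..k_max)."""
    if k_max is None:
        k_max = len(ranking.order)
    if k_max <= 0:
        raise ValidationError("k_max must be positive")
    if k_max > len(ranking.order):
        raise ValidationError(
            f"k_max={k_max} exceeds ranking length {len(ranking.order)}"
        )
    points = []
    for k in range(1, k_max + 1):
        result = jackknife_accuracy(matrix, labels, ranking.order[:k], scale=scale)
        points.append((k, result))
    return IfsCurve(points, ranking)


def ifs_fold_ranked(
    matrix: FeatureMatrix,
    labels: LabelVector,
    k_max: int,
    rule=None,
    scale: str = "minmax",
) -> IfsCurve:
    """IFS with the feature ranking recomputed inside every jackknife fold.

    The default workflow ranks once on the full labeled dataset (the
    ranking precedes cross-validation), which leaks label information into
    the evaluation; this nested variant re-runs the mRMR ranking on each
    training fold so the held-out sample never influences feature choice.
    Costs one full ranking per sample - intended for bias checks at small n.
    """
    from .mrmr import DiscretizationRule, mrmr_rank

    if rule is None:
        rule = DiscretizationRule()
    n = matrix.n_samples
    if k_max <= 0 or k_max > matrix.n_features:
        raise ValidationError("k_max must lie in 1..n_features")
    labels.require_both_classes()
    y = labels.labels
    correct = np.zeros((k_max, 2), dtype=int)  # columns: low, high
    idx = np.arange(n)
    for i in range(n):
        rows = idx != i
        train = FeatureMatrix(
            [matrix.sample_ids[j] for j in idx[rows]],
            matrix.feature_names,
            matrix.values[rows],
            matrix.missing_mask[rows],
        )
        train_labels = LabelVector(y[rows])
        ranking = mrmr_rank(train, train_labels, top_k=k_max, rule=rule)
        sub_train = train.subset(ranking.order)
        sub_query = matrix.subset(ranking.order)
        qv, qm = sub_query.values[i], sub_query.missing_mask[i]
        for k in range(1, k_max + 1):
            pred = _predict_one(
                sub_train.values[:, :k],
                sub_train.missing_mask[:, :k],
                train_labels,
                qv[:k],
                qm[:k],
                scale,
            )
            if pred == y[i]:
                correct[k - 1, int(y[i] == HIGH)] += 1
    points = []
    for k in range(1, k_max + 1):
        points.append(
            (
                k,
                EvalResult(
                    correct_high=int(correct[k - 1, 1]),
                    correct_low=int(correct[k - 1, 0]),
                    n_high=labels.n_high,
                    n_low=labels.n_low,
                ),
            )
        )
    # per-fold rankings differ, so the curve carries no single ranking
    return IfsCurve(points, None)


def _predict_one(
    train_values: np.ndarray,
    train_miss: np.ndarray,
    train_labels: LabelVector,
    query_values: np.ndarray,
    query_mask: np.ndarray,
    scale: str,
) -> str:
    miss = train_miss
    X0 = np.where(miss, 0.0, train_values)
    count = (~miss).sum(axis=0)
    mean = np.divide(
        X0.sum(axis=0), count, out=np.zeros(train_values.shape[1]), where=count > 0
    )
    Xtr = X0 + miss * mean
    xq = np.where(query_mask | np.isnan(query_values), mean, query_values)
    if scale == "minmax":
        lo = Xtr.min(axis=0)
        span = Xtr.max(axis=0) - lo
        span[span == 0] = 1.0
        Xtr = (Xtr - lo) / span
        xq = (xq - lo) / span
    return str(
        train_labels.labels[int(np.argmin(_cosine_distances(Xtr, xq)))]
    )


def optimal_feature_set(curve: IfsCurve) -> tuple[int, float, list[str]]:
    """The subset size at the accuracy peak (ties to the smallest k)."""
    if not curve.points:
        raise ValidationError("empty IFS curve")
    best_k, best_result = curve.points[0]
    for k, result in curve.points[1:]:
        if result.accuracy > best_result.accuracy:
            best_k, best_result = k, result
    names = curve.ranking.order[:best_k] if curve.ranking is not None else []
    return best_k, best_result.accuracy, names
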