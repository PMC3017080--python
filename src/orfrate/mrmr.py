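"""Maximum-relevance minimum-redundancy (mRMR) feature ranking.

Features are ranked greedily: the first feature maximizes mutual information
(MI) with the class (relevance); each later round picks the candidate
maximizing

    relevance(f) - mean_{s in selected} MI(f, s)        (difference form)

or, optionally, the quotient relevance / redundancy.  MI is the plug-in
estimate on discretized features, in bits.  Continuous features are
discretized into three states at mean +/- alpha * sd (alpha = 1 by default),
with a dedicated fourth state for missing values; an equal-frequency binning
rule is also available.  The rank of a feature is the round in which it was
selected - smaller rank means more important.

Ranking is computed once on the full labeled dataset (it precedes the
cross-validation loop); a fold-internal mode is available through the
pipeline for leakage-sensitive analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import FeatureMatrix, LabelVector, RankedFeatures
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: category index reserved for missing values after discretization
MISSING_STATE = 3


@dataclass(frozen=True)
class DiscretizationRule:
    """How continuous features are mapped to categories before MI estimation.

    ``three_state_mean_sigma``: below mean - alpha*sd -> 0, above
    mean + alpha*sd -> 2, else 1.  ``equal_frequency_k``: k quantile bins.
    """

    scheme: str = "three_state_mean_sigma"
    alpha: float = 1.0
    k: int = 3

    def __post_init__(self) -> None:
        if self.scheme not in ("three_state_mean_sigma", "equal_frequency_k"):
            raise ValidationError(f"unknown discretization scheme {self.scheme!r}")
        if self.alpha < 0:
            raise ValidationError("alpha must be nonnegative")
        if self.k < 2:
            raise ValidationError("equal-frequency binning needs k >= 2")


def discretize(
    values: np.ndarray,
    rule: DiscretizationRule = DiscretizationRule(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Categorical encoding of one feature; missing entries get their own state."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isnan(values)
    else:
        mask = np.asarray(mask, dtype=bool) | np.isnan(values)
    observed = values[~mask]
    if observed.size < 2:
        raise ValidationError("discretize needs at least 2 non-missing values")
    out = np.full(values.shape, MISSING_STATE, dtype=int)
    if np.ptp(observed) == 0:
        logger.warning("constant feature: all observations map to the middle state")
        out[~mask] = 1
        return out
    if rule.scheme == "three_state_mean_sigma":
        mean = observed.mean()
        sd = observed.std()
        lo, hi = mean - rule.alpha * sd, mean + rule.alpha * sd
        states = np.ones(values.shape, dtype=int)
        states[values < lo] = 0
        states[values > hi] = 2
        out[~mask] = states[~mask]
    else:
        edges = np.quantile(observed, np.linspace(0, 1, rule.k + 1)[1:-1])
        out[~mask] = np.searchsorted(edges, observed, side="right")
    return out


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information between two categorical vectors, in bits."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValidationError("empty vectors")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    return _mi_compact(xi, yi, xi.max() + 1, yi.max() + 1)


def _mi_compact(xi: np.ndarray, yi: np.ndarray, nx: int, ny: int) -> float:
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).astype(float)
    joint = joint.reshape(nx, ny) / xi.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(
        (joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])).sum()
    )
    return max(mi, 0.0)


def relevance(feature: np.ndarray, labels: LabelVector) -> float:
    """MI between one (discretized) feature and the class labels."""
    return mutual_information(feature, labels.as_binary())


def redundancy(feature: np.ndarray, selected: list[np.ndarray]) -> float:
    """Mean MI between a feature and an already-selected set; 0 when empty."""
    if not selected:
        return 0.0
    return float(np.mean([mutual_information(feature, s) for s in selected]))


def mrmr_rank(
    matrix: FeatureMatrix,
    labels: LabelVector,
    top_k: int | None = None,
    rule: DiscretizationRule = DiscretizationRule(),
    criterion: str = "difference",
) -> RankedFeatures:
    """Greedy mRMR ranking of the matrix columns against the labels.

    Ties in the criterion break by higher relevance, then by lexicographic
    feature name, so the ranking is reproducible and invariant to input
    column order.  Scores are compared at 1e-12 resolution so that exact
    mathematical ties cannot be reordered by floating-point summation noise.
    """
    if top_k is None:
        top_k = matrix.n_features
    if top_k <= 0:
        raise ValidationError("top_k must be positive")
    if top_k > matrix.n_features:
        raise ValidationError(
            f"top_k={top_k} exceeds feature count {matrix.n_features}"
        )
    if criterion not in ("difference", "quotient"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    if len(labels) != matrix.n_samples:
        raise ValidationError("label length does not match sample count")
    labels.require_both_classes()

    names = matrix.feature_names
    p = matrix.n_features
    disc = np.empty((matrix.n_samples, p), dtype=int)
    for j in range(p):
        disc[:, j] = discretize(matrix.values[:, j], rule, matrix.missing_mask[:, j])
    n_states = MISSING_STATE + 1
    y = labels.as_binary()

    rel = np.array([_mi_compact(disc[:, j], y, n_states, 2) for j in range(p)])
    relevance_map = {names[j]: float(rel[j]) for j in range(p)}

    order: list[str] = []
    score_at_selection: dict[str, float] = {}
    remaining = list(range(p))
    red_sum = np.zeros(p)
    for round_no in range(top_k):
        best_j = None
        best_key = None
        for j in remaining:
            if round_no == 0:
                score = rel[j]
            elif criterion == "difference":
                score = rel[j] - red_sum[j] / round_no
            else:
                score = rel[j] / max(red_sum[j] / round_no, 1e-12)
            key = (-round(score, 12), -round(rel[j], 12), names[j])
            if best_key is None or key < best_key:
                best_key = key
                best_j = j
        assert best_j is not None and best_key is not None
        order.append(names[best_j])
        score_at_selection[names[best_j]] = -best_key[0]
        remaining.remove(best_j)
        chosen = disc[:, best_j]
        for j in remaining:
            red_sum[j] += _mi_compact(disc[:, j], chosen, n_states, n_states)
    return RankedFeatures(order, relevance_map, score_at_selection)
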