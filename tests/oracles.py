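"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in plain Python (math/Counter,
explicit enumeration) and kept free of the package's numerical code paths.
"""

from __future__ import annotations

import math
from collections import Counter


def hypergeom_tail(universe: int, term: int, neighborhood: int, overlap: int) -> float:
    """P(X >= overlap) by exhaustive summation of binomial coefficients."""
    total = math.comb(universe, neighborhood)
    upper = min(term, neighborhood)
    return sum(
        math.comb(term, i) * math.comb(universe - term, neighborhood - i)
        for i in range(overlap, upper + 1)
    ) / total


def ctd(seq: list[int], groups: int) -> dict[str, float]:
    """Composition/transition/distribution by direct enumeration."""
    length = len(seq)
    out: dict[str, float] = {}
    for g in range(1, groups + 1):
        out[f"comp.g{g}"] = sum(1 for s in seq if s == g) / length
    pairs = [(1, 2)] if groups == 2 else [(1, 2), (1, 3), (2, 3)]
    for i, j in pairs:
        count = sum(
            1
            for a, b in zip(seq, seq[1:])
            if (a, b) == (i, j) or (a, b) == (j, i)
        )
        out[f"trans.g{i}{j}"] = count / (length - 1)
    landmark_names = ["first", "q25", "q50", "q75", "last"]
    n_landmarks = 5 if groups == 3 else 4
    dist_groups = range(1, groups + 1) if groups == 3 else [1]
    for g in dist_groups:
        occ = [pos + 1 for pos, s in enumerate(seq) if s == g]
        if not occ:
            values = [0.0] * 5
        else:
            n = len(occ)
            values = [
                occ[0] / length,
                occ[math.ceil(0.25 * n) - 1] / length,
                occ[math.ceil(0.50 * n) - 1] / length,
                occ[math.ceil(0.75 * n) - 1] / length,
                occ[-1] / length,
            ]
        for name, value in zip(landmark_names[:n_landmarks], values[:n_landmarks]):
            out[f"dist.g{g}.{name}"] = value
    return out


def mutual_information(x: list, y: list) -> float:
    """Plug-in MI in bits from raw counts."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    mi = 0.0
    for (a, b), c in joint.items():
        pxy = c / n
        mi += pxy * math.log2(pxy / ((px[a] / n) * (py[b] / n)))
    return max(mi, 0.0)


def discretize_three_state(values: list[float], alpha: float) -> list[int]:
    """Mean +/- alpha*sd three-state binning (population sd), plain Python."""
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / n)
    if all(v == values[0] for v in values):
        return [1] * n
    lo, hi = mean - alpha * sd, mean + alpha * sd
    return [0 if v < lo else 2 if v > hi else 1 for v in values]


def mrmr_order(
    columns: dict[str, list[float]],
    labels: list[int],
    top_k: int,
    alpha: float = 0.0,
) -> list[str]:
    """Greedy mRMR re-derived from scratch each round (difference form).

    Ties break by higher relevance, then lexicographic name - the documented
    rule.  Discretization follows the three-state mean/sd rule.
    """
    disc = {name: discretize_three_state(col, alpha) for name, col in columns.items()}
    relevance = {name: mutual_information(d, labels) for name, d in disc.items()}
    selected: list[str] = []
    while len(selected) < top_k:
        best = None
        for name in sorted(columns):
            if name in selected:
                continue
            if not selected:
                score = relevance[name]
            else:
                score = relevance[name] - sum(
                    mutual_information(disc[name], disc[s]) for s in selected
                ) / len(selected)
            # scores compared at 1e-12 resolution, mirroring the documented rule
            key = (-round(score, 12), -round(relevance[name], 12), name)
            if best is None or key < best[0]:
                best = (key, name)
        selected.append(best[1])
    return selected


def cosine_distance(x: list[float], y: list[float]) -> float:
    nx = math.sqrt(sum(a * a for a in x))
    ny = math.sqrt(sum(b * b for b in y))
    if nx == 0 or ny == 0:
        return 2.0
    return 1.0 - sum(a * b for a, b in zip(x, y)) / (nx * ny)


def nearest_neighbor_label(
    train: list[list[float]], labels: list[str], query: list[float]
) -> str:
    """Exhaustive scan; distance ties resolve to the earliest training row."""
    best_i = 0
    best_d = cosine_distance(train[0], query)
    for i in range(1, len(train)):
        d = cosine_distance(train[i], query)
        if d < best_d:
            best_i, best_d = i, d
    return labels[best_i]
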