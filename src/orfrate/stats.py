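"""Class labeling and feature-class association statistics.

The continuous translation rates are dichotomized at the median: ORFs at or
below the median form the low class, the rest the high class.  The direction
of association between a continuous feature X and the binary class is then
the point-biserial correlation

    r_pb = (M1 - M0) / s * sqrt(p (1 - p))

with M1/M0 the feature means in the high/low class, p the high-class
proportion and s the population (divide-by-n) standard deviation of X.
Under the population-sd convention r_pb equals the Pearson correlation
between X and the 0/1 class indicator exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, HIGH, LOW, LabelVector
from .errors import ValidationError

logger = logging.getLogger(__name__)


def median_split(rates: np.ndarray) -> LabelVector:
    """Label each sample low (<= median) or high (> median).

    The median is the standard middle order statistic (mean of the two
    central values for even n).  An all-identical input degenerates to all
    low with a logged warning.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ValidationError("median split needs at least 2 values")
    if np.isnan(rates).any():
        raise ValidationError("rates contain NaN")
    median = float(np.median(rates))
    labels = np.where(rates > median, HIGH, LOW)
    if (labels == LOW).all():
        logger.warning("degenerate median split: all samples labeled low")
    return LabelVector(labels, rule={"kind": "median_split", "median": median})


def point_biserial(
    feature: np.ndarray, labels: LabelVector, sd: str = "population"
) -> float:
    """Point-biserial correlation between a feature and the class labels.

    Positive when large feature values associate with the high class.
    ``sd`` selects the population (default) or sample standard-deviation
    convention.
    """
    feature = np.asarray(feature, dtype=float)
    if len(feature) != len(labels):
        raise ValidationError("feature and label lengths differ")
    labels.require_both_classes()
    if sd not in ("population", "sample"):
        raise ValidationError(f"unknown sd convention {sd!r}")
    high = labels.labels == HIGH
    observed = ~np.isnan(feature)
    if not observed.all():
        high = high[observed]
        feature = feature[observed]
        if high.all() or not high.any():
            raise ValidationError("a class has no observed values for this feature")
    s = feature.std(ddof=0 if sd == "population" else 1)
    if s == 0:
        raise ValidationError("zero standard deviation: correlation undefined")
    p = high.mean()
    m1 = feature[high].mean()
    m0 = feature[~high].mean()
    return float((m1 - m0) / s * np.sqrt(p * (1.0 - p)))


def correlation_report(
    matrix: FeatureMatrix, labels: LabelVector, features: list[str] | None = None
) -> pd.DataFrame:
    """Point-biserial coefficient per feature (constant features come back NaN)."""
    if features is None:
        features = matrix.feature_names
    rows = []
    for name in features:
        values, _ = matrix.column(name)
        try:
            r = point_biserial(values, labels)
        except ValidationError:
            r = float("nan")
        rows.append(
            {"feature": name, "r_pb": r, "n_high": labels.n_high, "n_low": labels.n_low}
        )
    return pd.DataFrame(rows)
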