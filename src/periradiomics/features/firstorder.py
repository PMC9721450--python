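"""First-order intensity statistics over a masked region."""

from __future__ import annotations

import numpy as np

from .config import FeatureConfig
from .discretize import discretize

FIRST_ORDER_NAMES = (
    "Mean", "Median", "Variance", "Skewness", "Kurtosis", "Energy",
    "Entropy", "Minimum", "Maximum", "Range", "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation", "RootMeanSquared", "Uniformity",
    "Percentile10", "Percentile90", "InterquartileRange", "RobustRange",
)


def first_order_features(image, mask, config: FeatureConfig | None = None):
    """18 first-order features of the in-mask intensity distribution.

    Moment-based features use population (1/N) moments. Skewness is
    ``m3 / m2^1.5`` and kurtosis ``m4 / m2^2`` (not excess); both are 0
    on a constant region. Entropy and uniformity are computed on the
    discretized level histogram so they share the texture bin settings.
    Robust MAD is the mean absolute deviation of the values inside the
    [P10, P90] band from that band's mean; robust range is P90 - P10.
    """
    if config is None:
        config = FeatureConfig()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    x = image[mask]
    if x.size == 0:
        raise ValueError("mask is empty")
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev ** 2)
    m3 = np.mean(dev ** 3)
    m4 = np.mean(dev ** 4)
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    kurt = m4 / m2 ** 2 if m2 > 0 else 0.0

    levels = discretize(image, mask, config)[mask]
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    band = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(band - band.mean()).mean()) if band.size else 0.0

    values = (
        float(mean), float(np.median(x)), float(m2), float(skew), float(kurt),
        float((x ** 2).sum()), entropy, float(x.min()), float(x.max()),
        float(x.max() - x.min()), float(np.abs(dev).mean()), rmad,
        float(np.sqrt((x ** 2).mean())), uniformity, float(p10), float(p90),
        float(p75 - p25), float(p90 - p10),
    )
    return dict(zip(FIRST_ORDER_NAMES, values))
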