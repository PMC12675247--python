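"""The 18 IBSI first-order intensity statistics.

Energy/entropy-type features use the discretized gray levels; moments and
percentiles use the (normalized) intensities directly.  Zero-variance
guards: skewness and kurtosis of a constant ROI are defined as 0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FIRST_ORDER_NAMES", "first_order_features"]

FIRST_ORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    values: np.ndarray, levels: np.ndarray, voxel_volume_mm3: float = 1.0
) -> dict[str, float]:
    """Compute the 18 first-order features of an ROI.

    ``values`` are the ROI intensities; ``levels`` the matching discretized
    gray levels (used for Entropy and Uniformity).
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    lv = np.asarray(levels).ravel()
    if lv.shape != x.shape:
        raise ValueError("values and levels must align")

    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    p = np.bincount(lv)[1:].astype(np.float64)
    p = p[p > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        m2 = var
        m3 = ((x - mean) ** 3).mean()
        m4 = ((x - mean) ** 4).mean()
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2
    else:
        skewness = 0.0
        kurtosis = 0.0

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume_mm3,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(median),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(skewness),
        "Kurtosis": float(kurtosis),
        "Variance": float(var),
        "Uniformity": uniformity,
    }
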