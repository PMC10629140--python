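"""The 18 first-order (intensity histogram and distribution) features.

Moments use population (1/n) estimators.  Skewness and kurtosis of a
constant region are undefined; both return a documented 0 sentinel so the
feature vector always has full length.  Entropy and Uniformity are computed
on the discretized histogram; everything else uses raw intensities.
"""

from __future__ import annotations

import numpy as np

from ..errors import EmptyMaskError
from .discretize import DiscretizedVolume, level_histogram

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
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
    values: np.ndarray,
    mask: np.ndarray,
    disc: DiscretizedVolume,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """Return the 18 named first-order features for the masked voxels.

    ``voxel_volume`` (mm^3) scales Energy into TotalEnergy.
    """
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(values, dtype=np.float64)[mask]
    if x.size == 0:
        raise EmptyMaskError("first-order features require a nonempty mask")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
    if var > 0:
        m = x - mean
        skew = float(np.mean(m**3) / var**1.5)
        kurt = float(np.mean(m**4) / var**2)
    else:
        skew = 0.0  # sentinel: undefined for a constant region
        kurt = 0.0
    p = level_histogram(disc, mask)
    nz = p[p > 0]
    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume) * energy,
        "Entropy": float(-np.sum(nz * np.log2(nz))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }
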