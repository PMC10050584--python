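"""First-order (histogram) statistics of voxel intensities inside a VOI."""

from __future__ import annotations

import numpy as np

from ..core import Mask3D, Volume3D
from .discretize import discretize

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES = (
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


def first_order_features(volume: Volume3D, voi: Mask3D, bin_width: float = 25.0) -> dict:
    """The 18 first-order features over VOI voxel values.

    Entropy and Uniformity are computed on the fixed-bin-width histogram
    (same discretization as the texture matrices); all other statistics
    use the raw values.  Skewness/Kurtosis use population moments with
    Kurtosis left non-excess (a Gaussian scores 3); for a constant region
    both default to 0.
    """
    if voi.is_empty():
        raise ValueError("first-order features require a non-empty VOI")
    x = volume.values[voi.values].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    diff = x - mean
    m2 = float(np.mean(diff**2))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    if m2 > 0:
        skew = float(np.mean(diff**3)) / m2**1.5
        kurt = float(np.mean(diff**4)) / m2**2
    else:
        skew, kurt = 0.0, 0.0

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    grid = discretize(volume, voi, bin_width)
    counts = np.bincount(grid.levels[voi.values])[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": volume.voxel_volume_mm3 * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(diff).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": uniformity,
    }
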