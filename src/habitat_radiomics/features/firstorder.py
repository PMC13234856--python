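"""First-order intensity statistics (18 features, pyradiomics active set)."""

from __future__ import annotations

import numpy as np

from .matrices import discretize

_EPS = np.spacing(1.0)

FIRSTORDER_NAMES = [
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
]


def firstorder_features(
    volume: np.ndarray, mask: np.ndarray, voxel_volume: float, bin_count: int = 32
) -> dict:
    """The 18 first-order features on the masked voxels.

    Entropy and uniformity use the fixed-bin-count discretized histogram;
    variance and the moment ratios use the population (1/N) convention;
    kurtosis is the plain (non-excess) fourth moment ratio, 3 for a
    Gaussian. Skewness and kurtosis of a constant region are 0.
    """
    x = volume[mask.astype(bool)].astype(float)
    n = x.size
    mean = x.mean()
    var = x.var()  # population
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    disc = discretize(volume, mask, bin_count)
    counts = np.bincount(disc[mask.astype(bool)])[1:]
    p = counts[counts > 0] / n
    skew = float(np.mean((x - mean) ** 3) / sd**3) if sd > 0 else 0.0
    kurt = float(np.mean((x - mean) ** 4) / var**2) if var > 0 else 0.0
    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(np.sum(x**2) * voxel_volume),
        "Entropy": float(-(p * np.log2(p + _EPS)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": float((p**2).sum()),
    }
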