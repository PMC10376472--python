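"""First-order intensity statistics of an ROI (18 features).

Computed on the normalised (0-256 rescaled) intensities; Entropy and
Uniformity use the fixed-bin-width discretized histogram so they share the
gray-level resolution of the texture families.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_EPS = np.spacing(1.0)

FIRSTORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def firstorder_features(values: np.ndarray, disc: np.ndarray,
                        voxel_volume: float) -> dict[str, float]:
    """``values``: ROI intensities; ``disc``: their discretized levels."""
    x = np.asarray(values, dtype=np.float64).ravel()
    out: dict[str, float] = {}
    out["Energy"] = float((x ** 2).sum())
    out["TotalEnergy"] = float(voxel_volume * (x ** 2).sum())
    levels, counts = np.unique(disc, return_counts=True)
    p = counts / counts.sum()
    out["Entropy"] = float(-(p * np.log2(p + _EPS)).sum())
    out["Minimum"] = float(x.min())
    out["10Percentile"] = float(np.percentile(x, 10))
    out["90Percentile"] = float(np.percentile(x, 90))
    out["Maximum"] = float(x.max())
    mean = float(x.mean())
    out["Mean"] = mean
    out["Median"] = float(np.median(x))
    out["InterquartileRange"] = float(np.percentile(x, 75) - np.percentile(x, 25))
    out["Range"] = float(x.max() - x.min())
    out["MeanAbsoluteDeviation"] = float(np.abs(x - mean).mean())
    lo, hi = np.percentile(x, [10, 90])
    xr = x[(x >= lo) & (x <= hi)]
    out["RobustMeanAbsoluteDeviation"] = float(np.abs(xr - xr.mean()).mean()) if xr.size else 0.0
    out["RootMeanSquared"] = float(np.sqrt((x ** 2).mean()))
    sd = x.std()
    out["Skewness"] = float(stats.skew(x)) if sd > 0 else 0.0
    # Pearson (non-excess) kurtosis; 0 by convention for a constant ROI
    out["Kurtosis"] = float(stats.kurtosis(x, fisher=False)) if sd > 0 else 0.0
    out["Variance"] = float(x.var())
    out["Uniformity"] = float((p ** 2).sum())
    return out
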