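"""Agreement analytics and file I/O: Bland-Altman, error-density tables, NIfTI/CSV.

Bland-Altman convention: for each record the x coordinate is the mean
(actual + predicted)/2 and the y coordinate the difference
actual - predicted.  With this orientation a segmentation whose true Dice
is 0 but whose predicted Dice is D lands at (D/2, -D): all such points lie
on the line y = -2x through the origin, a useful diagnostic locus for
false-positive segmentations of empty regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import ImageVolume, LabelVolume

__all__ = [
    "BlandAltmanResult",
    "bland_altman",
    "density_summary",
    "save_nifti",
    "load_image",
    "load_labels",
    "write_manifest",
]


@dataclass
class BlandAltmanResult:
    points: np.ndarray  # (n, 2): mean, diff
    mean_diff: float
    loa_low: float
    loa_high: float


def bland_altman(actual, predicted, diff_sign: str = "actual-predicted") -> BlandAltmanResult:
    """Bland-Altman agreement of predicted vs actual Dice.

    Limits of agreement are mean_diff +/- 1.96 * SD(diff) (population SD).
    ``diff_sign`` may be flipped to "predicted-actual" if a different
    orientation is preferred.
    """
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape or a.size < 2:
        raise ValueError("need >= 2 paired records of equal length")
    diff = a - p if diff_sign == "actual-predicted" else p - a
    mean = (a + p) / 2.0
    md = float(diff.mean())
    sd = float(diff.std())
    return BlandAltmanResult(points=np.column_stack([mean, diff]), mean_diff=md,
                             loa_low=md - 1.96 * sd, loa_high=md + 1.96 * sd)


def density_summary(table: pd.DataFrame, stratify_by: str, n_bins: int = 10,
                    error_col: str = "abs_error") -> pd.DataFrame:
    """Per-stratum histogram of absolute prediction error with shared bins.

    Returns a tidy frame (stratum, bin_left, bin_right, count, proportion);
    in "filled" reading, proportions of all strata sum to 1 within each bin.
    """
    if stratify_by not in table.columns:
        raise ValueError(f"unknown stratifier {stratify_by!r}; columns: {list(table.columns)}")
    if table.empty:
        raise ValueError("empty table")
    err = table[error_col].to_numpy(np.float64)
    edges = np.histogram_bin_edges(err, bins=n_bins)
    rows = []
    totals = np.histogram(err, bins=edges)[0]
    for stratum, sub in table.groupby(stratify_by):
        counts = np.histogram(sub[error_col].to_numpy(np.float64), bins=edges)[0]
        for b in range(n_bins):
            rows.append({"stratum": stratum, "bin_left": edges[b], "bin_right": edges[b + 1],
                         "count": int(counts[b]),
                         "proportion": counts[b] / totals[b] if totals[b] else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI / CSV round-trips


def save_nifti(vol: ImageVolume | LabelVolume, path) -> None:
    """Write a volume as NIfTI with spacing in the affine (labels as int16)."""
    is_label = isinstance(vol, LabelVolume)
    data = vol.grid.astype(np.int16) if is_label else vol.grid.astype(np.float32)
    # our axis order is (z, y, x); NIfTI convention is (x, y, z)
    affine = np.diag([vol.spacing[2], vol.spacing[1], vol.spacing[0], 1.0])
    nib.save(nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine), str(path))


def _load(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    return data, (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def load_image(path) -> ImageVolume:
    data, spacing = _load(path)
    return ImageVolume(data.astype(np.float64), spacing)


def load_labels(path) -> LabelVolume:
    data, spacing = _load(path)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"{path}: non-integer values in a label volume")
        data = rounded
    return LabelVolume(data.astype(np.int16), spacing)


def write_manifest(path, seed: int, settings: dict) -> None:
    """Record versions, seed and settings alongside a run's outputs."""
    import sklearn
    import scipy
    import skimage

    manifest = {
        "seed": seed,
        "settings": settings,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
            "nibabel": nib.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
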