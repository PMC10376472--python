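"""Image preprocessing and whole-heart weighted centre-of-mass cropping.

The localisation step replaces a dedicated localisation network with
mask-driven geometry: the whole-heart mask is the union of the structure
labels, each slice contributes its foreground pixel count W_j and in-plane
centroid (X_j, Y_j), and the subject-level crop centre is the pixel-count
weighted average of the slice centroids,

    X_center = sum_j W_j X_j / sum_j W_j    (and likewise Y_center).

Coordinate convention everywhere: (row = y, col = x), 0-based indices,
half-open crop windows.  Volumes are (slices, rows, cols) with spacing
(z, y, x) in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "STRUCTURES",
    "SliceMass",
    "CropWindow",
    "resample_inplane",
    "clahe_equalize",
    "minmax_normalize",
    "slice_masses",
    "weighted_center_of_mass",
    "crop_fixed",
]


@dataclass
class ImageVolume:
    """A 3D scalar grid (slices x rows x cols) with per-axis spacing in mm."""

    grid: np.ndarray
    spacing: tuple[float, float, float]  # (z, y, x) mm

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.grid.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        if np.issubdtype(self.grid.dtype, np.floating) and not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.grid.min()), float(self.grid.max())


#: ACDC-style label convention for the three segmented structures.
STRUCTURES = {"RVC": 1, "MYO": 2, "LVC": 3}


@dataclass
class LabelVolume:
    """Integer label grid sharing geometry with a companion :class:`ImageVolume`.

    Labels: 0 = background, 1 = RVC, 2 = MYO, 3 = LVC (ACDC convention).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3D label grid, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError(f"label grid must be integer, got dtype {self.grid.dtype}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    def structure_mask(self, structure: str | int) -> np.ndarray:
        """Boolean mask of a single structure (by name or label id)."""
        label = STRUCTURES[structure] if isinstance(structure, str) else int(structure)
        return self.grid == label

    def whole_heart(self) -> np.ndarray:
        """Union of all structure labels (the localisation foreground)."""
        return self.grid > 0


@dataclass(frozen=True)
class SliceMass:
    """Per-slice foreground mass: pixel count and in-plane centroid."""

    slice_index: int
    weight: int
    com: tuple[float, float] | None  # (row, col); None when weight == 0


@dataclass(frozen=True)
class CropWindow:
    """A fixed-size half-open in-plane window [r0, r1) x [c0, c1)."""

    center: tuple[float, float]  # (row, col) as given, pre-rounding
    size: int
    bounds: tuple[tuple[int, int], tuple[int, int]] = field(default=None)  # type: ignore[assignment]


def resample_inplane(img: ImageVolume, target: float = 1.0, kind: str = "linear") -> ImageVolume:
    """Resample the in-plane (row, col) axes to ``target`` mm; z untouched.

    ``kind="linear"`` for intensity images, ``"nearest"`` for label volumes
    (preserves the label set).
    """
    if target <= 0:
        raise ValueError(f"target spacing must be positive, got {target}")
    if kind not in ("linear", "nearest"):
        raise ValueError(f"kind must be 'linear' or 'nearest', got {kind!r}")
    zf = (1.0, img.spacing[1] / target, img.spacing[2] / target)
    if np.allclose(zf, 1.0):
        return ImageVolume(img.grid.copy(), img.spacing)
    order = 1 if kind == "linear" else 0
    out = ndimage.zoom(img.grid, zf, order=order, mode="nearest", grid_mode=True)
    if kind == "nearest":
        out = out.astype(img.grid.dtype, copy=False)
    return ImageVolume(out, (img.spacing[0], target, target))


def clahe_equalize(img: ImageVolume, clip: float = 0.01, tiles: int = 8) -> ImageVolume:
    """Per-slice contrast-limited adaptive histogram equalisation.

    Output intensities are in [0, 1].  A constant slice maps to a constant
    slice (no contrast to redistribute).  Deterministic for fixed parameters.
    """
    out = np.empty(img.grid.shape, dtype=np.float64)
    for k in range(img.grid.shape[0]):
        sl = img.grid[k].astype(np.float64)
        lo, hi = sl.min(), sl.max()
        if hi == lo:
            out[k] = 0.0
            continue
        sl01 = (sl - lo) / (hi - lo)
        out[k] = exposure.equalize_adapthist(sl01, kernel_size=None if tiles <= 0 else
                                             tuple(max(1, s // tiles) for s in sl.shape),
                                             clip_limit=clip)
    return ImageVolume(out, img.spacing)


def minmax_normalize(img: ImageVolume) -> ImageVolume:
    """Volume-wise (v - min) / (max - min); a constant volume maps to zeros."""
    g = img.grid.astype(np.float64)
    lo, hi = g.min(), g.max()
    if hi == lo:
        return ImageVolume(np.zeros_like(g), img.spacing)
    return ImageVolume((g - lo) / (hi - lo), img.spacing)


def slice_masses(mask: np.ndarray) -> list[SliceMass]:
    """Per-slice foreground pixel counts and centroids of a 3D boolean mask."""
    m = np.asarray(mask).astype(bool)
    if m.ndim != 3:
        raise ValueError(f"expected a 3D mask, got shape {m.shape}")
    out = []
    for j in range(m.shape[0]):
        w = int(m[j].sum())
        com = tuple(map(float, ndimage.center_of_mass(m[j]))) if w else None
        out.append(SliceMass(slice_index=j, weight=w, com=com))
    return out


def weighted_center_of_mass(masses: list[SliceMass]) -> tuple[float, float]:
    """Pixel-count weighted average of slice centroids -> (row, col).

    Equals the in-plane centroid of the whole 3D foreground.
    """
    total = sum(m.weight for m in masses)
    if total == 0:
        raise ValueError("no foreground to localize: all slice weights are zero")
    r = sum(m.weight * m.com[0] for m in masses if m.weight) / total
    c = sum(m.weight * m.com[1] for m in masses if m.weight) / total
    return (r, c)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def make_window(center: tuple[float, float], size: int) -> CropWindow:
    """Half-open window of exactly ``size`` pixels per axis around ``center``.

    The centre is rounded half-away-from-zero to an integer pixel first;
    sub-pixel cropping would force interpolation.
    """
    if size <= 0 or size % 2:
        raise ValueError(f"size must be a positive even integer, got {size}")
    h = size // 2
    bounds = tuple((_round_half_away(c) - h, _round_half_away(c) + h) for c in center)
    return CropWindow(center=tuple(map(float, center)), size=size, bounds=bounds)  # type: ignore[arg-type]


def crop_fixed(img: ImageVolume, center: tuple[float, float], size: int = 160,
               pad_value: float = 0.0) -> ImageVolume:
    """Crop every slice to a fixed ``size x size`` window around ``center``.

    Regions outside the image are padded with ``pad_value``.  Apply the same
    call with the same centre to a companion label volume (pad_value=0) to
    keep image and labels aligned.
    """
    win = make_window(center, size)
    (r0, r1), (c0, c1) = win.bounds
    nz, nr, nc = img.grid.shape
    out = np.full((nz, size, size), pad_value, dtype=img.grid.dtype)
    sr0, sr1 = max(r0, 0), min(r1, nr)
    sc0, sc1 = max(c0, 0), min(c1, nc)
    if sr0 < sr1 and sc0 < sc1:
        out[:, sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = img.grid[:, sr0:sr1, sc0:sc1]
    return ImageVolume(out, img.spacing)
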