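"""Shape descriptors in physical (mm) units: 9 in 2D, 14 in 3D.

Surface/perimeter quantities come from marching-squares / marching-cubes
meshes of the binary mask; axis lengths from the eigenvalues of the
physical-coordinate covariance (principal-component axes, 4*sqrt(lambda)).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

SHAPE2D_FEATURES = (
    "MeshSurface", "PixelSurface", "Perimeter", "PerimeterSurfaceRatio",
    "Sphericity", "MaximumDiameter", "MajorAxisLength", "MinorAxisLength",
    "Elongation",
)

SHAPE3D_FEATURES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)

_EPS = 1e-12


def _axis_lengths(coords_mm: np.ndarray) -> np.ndarray:
    """Descending principal axis lengths 4*sqrt(eigenvalue) of the coords."""
    if coords_mm.shape[0] < 2:
        return np.zeros(coords_mm.shape[1])
    cov = np.cov(coords_mm, rowvar=False)
    ev = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
    return 4.0 * np.sqrt(np.clip(ev, 0.0, None))


def _max_pairwise(points: np.ndarray) -> float:
    if points.shape[0] < 2:
        return 0.0
    pts = points
    if pts.shape[0] > 16:
        try:
            pts = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (collinear/coplanar) point sets
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def shape2d_features(mask: np.ndarray, spacing: tuple[float, float]) -> dict[str, float]:
    """9 planar shape features; ``spacing`` = (row, col) mm."""
    m = np.asarray(mask, dtype=bool)
    sy, sx = spacing
    pixel_area = sy * sx
    out: dict[str, float] = {}
    out["PixelSurface"] = float(m.sum() * pixel_area)

    padded = np.pad(m.astype(float), 1)
    contours = measure.find_contours(padded, 0.5, positive_orientation="high")
    area = 0.0
    perimeter = 0.0
    for c in contours:
        phys = (c - 1.0) * np.array([sy, sx])
        ys, xs = phys[:, 0], phys[:, 1]
        area += 0.5 * np.sum(xs[:-1] * ys[1:] - xs[1:] * ys[:-1])
        perimeter += float(np.sqrt((np.diff(phys, axis=0) ** 2).sum(axis=1)).sum())
    area = abs(area)
    out["MeshSurface"] = area if area > _EPS else pixel_area * m.sum()
    out["Perimeter"] = perimeter
    out["PerimeterSurfaceRatio"] = perimeter / max(out["MeshSurface"], _EPS)
    out["Sphericity"] = 2.0 * np.sqrt(np.pi * out["MeshSurface"]) / max(perimeter, _EPS)

    coords = np.argwhere(m) * np.array([sy, sx])
    boundary = np.vstack([(c - 1.0) * np.array([sy, sx]) for c in contours]) if contours else coords
    out["MaximumDiameter"] = _max_pairwise(boundary)
    ax = _axis_lengths(coords)
    out["MajorAxisLength"] = float(ax[0])
    out["MinorAxisLength"] = float(ax[1])
    out["Elongation"] = float(np.sqrt(ax[1] / ax[0])) if ax[0] > 0 else 1.0
    return out


def shape3d_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """14 volumetric shape features; ``spacing`` = (z, row, col) mm."""
    m = np.asarray(mask, dtype=bool)
    voxel_volume = float(np.prod(spacing))
    out: dict[str, float] = {}
    out["VoxelVolume"] = float(m.sum() * voxel_volume)

    padded = np.pad(m.astype(float), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
        verts -= np.array(spacing)  # undo the pad offset
        surface = float(measure.mesh_surface_area(verts, faces))
        tri = verts[faces]
        mesh_volume = float(abs(np.einsum("ij,ij->i", tri[:, 0],
                                          np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    except (ValueError, RuntimeError):  # mask too thin for a closed mesh
        verts = (np.argwhere(m).astype(float)) * np.array(spacing)
        surface = 6.0 * voxel_volume ** (2 / 3) * m.sum()
        mesh_volume = out["VoxelVolume"]
    out["MeshVolume"] = mesh_volume if mesh_volume > _EPS else out["VoxelVolume"]
    out["SurfaceArea"] = surface
    out["SurfaceVolumeRatio"] = surface / max(out["MeshVolume"], _EPS)
    out["Sphericity"] = (36.0 * np.pi * out["MeshVolume"] ** 2) ** (1.0 / 3.0) / max(surface, _EPS)

    out["Maximum3DDiameter"] = _max_pairwise(verts)
    # planar maximum diameters: distances restricted to two of the three axes
    out["Maximum2DDiameterSlice"] = _max_pairwise(verts[:, 1:])          # row-col plane
    out["Maximum2DDiameterColumn"] = _max_pairwise(verts[:, [0, 1]])     # z-row plane
    out["Maximum2DDiameterRow"] = _max_pairwise(verts[:, [0, 2]])        # z-col plane

    coords = np.argwhere(m) * np.array(spacing)
    ax = _axis_lengths(coords)
    out["MajorAxisLength"] = float(ax[0])
    out["MinorAxisLength"] = float(ax[1])
    out["LeastAxisLength"] = float(ax[2])
    out["Elongation"] = float(np.sqrt(ax[1] / ax[0])) if ax[0] > 0 else 1.0
    out["Flatness"] = float(np.sqrt(ax[2] / ax[0])) if ax[0] > 0 else 1.0
    return out
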