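"""Synthetic short-axis cardiac phantoms and a calibrated mask-perturbation engine.

The phantom emulates an end-diastolic short-axis cine stack: 6-12 slices
covering the ventricles base to apex, each slice holding an LV-cavity disk,
a myocardial annulus around it, and an RV-cavity crescent abutting the
annulus.  Structure radii shrink monotonically towards the apex.  Image
intensities are per-tissue means plus Gaussian noise and a smooth
low-frequency field, so texture statistics inside a candidate mask shift
measurably when the mask leaks into the wrong tissue.

The perturbation engine stands in for segmentation networks of varying
quality: graded morphological and geometric degradations of the ground-truth
mask produce candidate segmentations whose Dice score against the truth
spans 0..1, and :func:`calibrate_severity` inverts a mode's severity knob to
hit a requested Dice value.  Disease presets (HCM, DCM, HHD) alter geometry
only, giving stratified evaluation something to stratify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_metrics import dsc
from .geometry import ImageVolume, LabelVolume, STRUCTURES

__all__ = [
    "PhantomParams",
    "PerturbationSpec",
    "PERTURBATION_MODES",
    "DISEASE_PRESETS",
    "generate_phantom",
    "generate_cohort",
    "perturb_mask",
    "calibrate_severity",
    "build_qc_dataset",
]

PERTURBATION_MODES = (
    "dilate", "erode", "boundary_jitter", "translate",
    "drop_apical", "drop_basal", "false_blob", "empty",
)

#: Geometry multipliers (LVC radius, MYO thickness) per disease preset.
#: HCM thickens the myocardium, DCM dilates the cavity with wall thinning,
#: HHD thickens the wall moderately; HC is the healthy reference.
DISEASE_PRESETS = {
    "HC": (1.0, 1.0),
    "HCM": (1.0, 1.8),
    "DCM": (1.5, 0.6),
    "HHD": (1.0, 1.4),
}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity and acquisition parameters of one phantom subject.

    Radii and thicknesses are in mm (the in-plane grid is ``inplane_mm``
    per pixel); intensities are arbitrary MR-like units.
    """

    n_slices: int = 9
    grid_size: int = 192
    lvc_radius_mm: float = 22.0
    myo_thickness_mm: float = 8.0
    rvc_radius_mm: float = 20.0
    apical_taper: float = 0.55  # apical radius = (1 - taper) * basal radius
    z_spacing_mm: float = 8.0
    inplane_mm: float = 1.0
    intensity_means: dict = field(default_factory=lambda: {
        0: 55.0,   # background / lung
        1: 185.0,  # RV blood pool
        2: 110.0,  # myocardium
        3: 200.0,  # LV blood pool
    })
    noise_sigma: float = 14.0
    preset: str = "HC"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (6 <= self.n_slices <= 12):
            raise ValueError(f"n_slices must be in 6..12, got {self.n_slices}")
        if not (6.0 <= self.z_spacing_mm <= 10.0):
            raise ValueError(f"z_spacing_mm must be in 6..10, got {self.z_spacing_mm}")
        if self.preset not in DISEASE_PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(DISEASE_PRESETS)}")
        if min(self.lvc_radius_mm, self.myo_thickness_mm, self.rvc_radius_mm) <= 0:
            raise ValueError("radii and thickness must be positive")


@dataclass(frozen=True)
class PerturbationSpec:
    """One graded degradation: mode, severity in [0, 1], and its RNG seed.

    Severity 0 is the identity for every mode except ``empty``.
    """

    mode: str
    severity: float
    seed: int = 0
    realized_dsc: float | None = None  # filled in by calibrate_severity

    def __post_init__(self) -> None:
        if self.mode not in PERTURBATION_MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {PERTURBATION_MODES}")
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def generate_phantom(p: PhantomParams) -> tuple[ImageVolume, LabelVolume]:
    """Build one synthetic subject: cine-like image stack plus labels {0,1,2,3}.

    Fully reproducible from ``p.seed``.  Raises when the geometry is
    impossible (myocardial annulus thinner than one pixel).
    """
    lvc_scale, myo_scale = DISEASE_PRESETS[p.preset]
    r_lvc = p.lvc_radius_mm * lvc_scale / p.inplane_mm
    th_myo = p.myo_thickness_mm * myo_scale / p.inplane_mm
    r_rvc = p.rvc_radius_mm / p.inplane_mm
    if th_myo < 1.5:
        raise ValueError(
            f"myocardial annulus {th_myo:.2f} px thick cannot enclose the cavity; need >= 1.5 px")

    rng = np.random.default_rng(p.seed)
    n, g = p.n_slices, p.grid_size
    # heart centre jittered per subject, kept away from the border
    cy = g / 2 + rng.uniform(-8, 8)
    cx = g / 2 + rng.uniform(-8, 8)

    labels = np.zeros((n, g, g), dtype=np.int8)
    for k in range(n):
        t = 1.0 - p.apical_taper * k / (n - 1)  # base -> apex shrink
        rl = r_lvc * t
        ro = rl + th_myo  # epicardial radius; wall thickness preserved
        rv = r_rvc * t
        lv_disk = _disk((g, g), (cy, cx), rl)
        epi_disk = _disk((g, g), (cy, cx), ro)
        # RV crescent: disk west of the epicardium, cut by the epicardial wall
        rv_center = (cy, cx - (ro + 0.55 * rv))
        rv_disk = _disk((g, g), rv_center, rv)
        sl = np.zeros((g, g), dtype=np.int8)
        sl[rv_disk & ~epi_disk] = STRUCTURES["RVC"]
        sl[epi_disk] = STRUCTURES["MYO"]
        sl[lv_disk] = STRUCTURES["LVC"]
        labels[k] = sl

    means = np.array([p.intensity_means[i] for i in range(4)], dtype=np.float64)
    img = means[labels]
    # smooth low-frequency field: coil-shading-like multiplicative variation
    lowfreq = ndimage.gaussian_filter(rng.standard_normal((n, g, g)), sigma=(0, 18, 18))
    img *= 1.0 + 0.08 * lowfreq
    img += rng.normal(0.0, p.noise_sigma, size=img.shape)
    img = ndimage.gaussian_filter(img, sigma=(0, 0.6, 0.6))  # mild PSF blur
    np.clip(img, 0.0, None, out=img)

    spacing = (p.z_spacing_mm, p.inplane_mm, p.inplane_mm)
    return ImageVolume(img, spacing), LabelVolume(labels, spacing)


def generate_cohort(n_subjects: int, seed: int = 0,
                    preset_mix: dict[str, float] | None = None,
                    **param_overrides) -> list[tuple[PhantomParams, ImageVolume, LabelVolume]]:
    """Generate a cohort with per-subject random geometry and disease preset.

    ``preset_mix`` maps preset name -> sampling probability (defaults to a
    balanced clinical-style mix).  Subject-level geometry (slice count,
    radii, z spacing) varies around the defaults.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    mix = preset_mix or {"HC": 0.4, "HCM": 0.2, "DCM": 0.2, "HHD": 0.2}
    names = sorted(mix)
    probs = np.array([mix[k] for k in names], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        preset = names[rng.choice(len(names), p=probs)]
        p = PhantomParams(
            n_slices=int(rng.integers(6, 13)),
            lvc_radius_mm=float(rng.uniform(18, 26)),
            myo_thickness_mm=float(rng.uniform(6, 10)),
            rvc_radius_mm=float(rng.uniform(16, 24)),
            z_spacing_mm=float(rng.uniform(6, 10)),
            preset=preset,
            seed=int(rng.integers(0, 2**31 - 1)),
            **param_overrides,
        )
        img, lab = generate_phantom(p)
        cohort.append((p, img, lab))
    return cohort


# ---------------------------------------------------------------------------
# perturbation engine


def _perturb_binary(mask: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Apply one degradation mode to a 3D boolean mask (slice-wise in-plane)."""
    rng = np.random.default_rng(spec.seed)
    s = spec.severity
    out = mask.copy()
    n = mask.shape[0]

    if spec.mode == "empty":
        return np.zeros_like(mask)
    if s == 0.0:
        return out

    if spec.mode in ("dilate", "erode"):
        iters = int(np.ceil(s * 8))
        op = ndimage.binary_dilation if spec.mode == "dilate" else ndimage.binary_erosion
        for k in range(n):
            if mask[k].any():
                out[k] = op(mask[k], iterations=iters)
    elif spec.mode == "boundary_jitter":
        amp = 14.0 * s  # typical signed-distance displacement (px) at severity 1
        for k in range(n):
            if not mask[k].any():
                continue
            inside = ndimage.distance_transform_edt(mask[k])
            outside = ndimage.distance_transform_edt(~mask[k])
            sdf = inside - outside
            noise = ndimage.gaussian_filter(rng.standard_normal(mask[k].shape), sigma=4.0)
            noise /= max(noise.std(), 1e-12)
            out[k] = (sdf + amp * noise) > 0
    elif spec.mode == "translate":
        shift = max(1, int(round(s * 24)))
        theta = rng.uniform(0, 2 * np.pi)
        dr = int(round(shift * np.sin(theta)))
        dc = int(round(shift * np.cos(theta)))
        if dr == 0 and dc == 0:
            dc = shift
        out = np.zeros_like(mask)
        for k in range(n):
            out[k] = np.roll(np.roll(mask[k], dr, axis=0), dc, axis=1)
            # rolled-in wrap regions are cleared
            if dr > 0:
                out[k, :dr, :] = False
            elif dr < 0:
                out[k, dr:, :] = False
            if dc > 0:
                out[k, :, :dc] = False
            elif dc < 0:
                out[k, :, dc:] = False
    elif spec.mode in ("drop_apical", "drop_basal"):
        k_drop = int(round(s * (n - 1)))
        if k_drop:
            if spec.mode == "drop_apical":
                out[n - k_drop:] = False
            else:
                out[:k_drop] = False
    elif spec.mode == "false_blob":
        radius = 3.0 + 14.0 * s
        n_slices_hit = max(1, int(round(s * n)))
        hit = rng.choice(n, size=min(n_slices_hit, n), replace=False)
        g = mask.shape[1:]
        for k in hit:
            cy = rng.uniform(radius, g[0] - radius)
            cx = rng.uniform(radius, g[1] - radius)
            out[k] |= _disk(g, (cy, cx), radius)
    return out


def perturb_mask(labels: LabelVolume, spec: PerturbationSpec,
                 structure: str | int) -> LabelVolume:
    """Degrade one structure of a label volume, leaving the rest untouched.

    The named structure's support is replaced by its perturbed version;
    where the perturbed structure expands it claims the pixels it covers
    (as a real mis-segmentation would).  Other structures' pixels outside
    that support are unchanged.
    """
    label = STRUCTURES[structure] if isinstance(structure, str) else int(structure)
    binary = labels.grid == label
    if not binary.any() and spec.mode != "empty":
        raise ValueError(f"structure {structure!r} absent from mask; only mode='empty' is valid")
    perturbed = _perturb_binary(binary, spec)
    out = labels.grid.copy()
    out[binary] = 0
    out[perturbed] = label
    return LabelVolume(out, labels.spacing)


def calibrate_severity(labels: LabelVolume, structure: str | int, target_dsc: float,
                       mode: str, seed: int = 0, tol: float = 0.05,
                       max_iter: int = 30) -> PerturbationSpec:
    """Bisection on severity until the realized Dice is within ``tol`` of target.

    Severity -> Dice is monotone decreasing for every mode, so plain
    bisection on [0, 1] converges.  Raises when the target lies outside the
    mode's achievable Dice range (e.g. dilation never reaches 0).
    """
    if not (0.0 <= target_dsc <= 1.0):
        raise ValueError(f"target_dsc must be in [0, 1], got {target_dsc}")
    gt = labels.structure_mask(structure)

    def realized(sev: float) -> float:
        spec = PerturbationSpec(mode=mode, severity=sev, seed=seed)
        pert = _perturb_binary(gt, spec)
        return dsc(pert, gt)

    if mode == "empty":
        got = realized(1.0)
        if abs(got - target_dsc) > tol:
            raise ValueError(f"mode 'empty' only reaches dsc={got:.3f}, not {target_dsc}")
        return PerturbationSpec(mode=mode, severity=1.0, seed=seed, realized_dsc=got)

    d_lo = realized(1.0)  # worst dice the mode can reach
    if target_dsc >= 1.0 - tol:
        return PerturbationSpec(mode=mode, severity=0.0, seed=seed, realized_dsc=1.0)
    if target_dsc < d_lo - tol:
        raise ValueError(
            f"target dsc {target_dsc} unreachable for mode {mode!r}: "
            f"achievable range is [{d_lo:.3f}, 1.0]")

    lo, hi = 0.0, 1.0  # dice(lo)=1 >= target >= dice(hi)
    best_sev, best_d = 1.0, d_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d = realized(mid)
        if abs(d - target_dsc) < abs(best_d - target_dsc):
            best_sev, best_d = mid, d
        if abs(d - target_dsc) <= tol:
            break
        if d > target_dsc:
            lo = mid
        else:
            hi = mid
    return PerturbationSpec(mode=mode, severity=best_sev, seed=seed, realized_dsc=best_d)


def expected_dataset_size(n_subjects: int, n_variants: int) -> int:
    """3D segmentations per structure a variant bank produces: one per
    subject per variant (e.g. 465 subjects x 32 model variants -> 14,880)."""
    if n_subjects < 1 or n_variants < 1:
        raise ValueError("need at least one subject and one variant")
    return n_subjects * n_variants


def variant_targets(n_variants: int, dsc_grid) -> list[float]:
    """Dice targets for a bank of ``n_variants`` degraded models.

    Few variants sample the grid evenly end to end; many variants cycle
    through it, so the realized Dice histogram always spans the grid's range.
    """
    grid = list(dsc_grid)
    if n_variants == 1:
        return [grid[-1]]
    if n_variants <= len(grid):
        idx = np.round(np.linspace(0, len(grid) - 1, n_variants)).astype(int)
        return [grid[i] for i in idx]
    return [grid[v % len(grid)] for v in range(n_variants)]


def _slice_records(pert: np.ndarray, gt: np.ndarray) -> list[dict]:
    recs = []
    for k in range(gt.shape[0]):
        p_any, g_any = bool(pert[k].any()), bool(gt[k].any())
        recs.append({
            "slice_index": k,
            "actual_dsc": dsc(pert[k], gt[k]),
            "empty_pair": not (p_any or g_any),
        })
    return recs


def build_qc_dataset(cohort, n_variants: int = 32,
                     dsc_grid: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
                     seed: int = 0, structures: tuple[str, ...] = ("RVC", "MYO", "LVC"),
                     keep_volumes: bool = True):
    """Emulate a bank of segmentation models of varying quality.

    For every subject x structure x variant one perturbed 3D segmentation is
    produced (severity calibrated to a Dice target cycled from ``dsc_grid``),
    together with its per-slice 2D Dice scores and the subject-level 3D Dice
    against ground truth.  Total 3D record count per structure is
    ``len(cohort) * n_variants``.

    Returns ``(segmentations, index)`` where ``segmentations`` maps
    (subject, structure, variant) -> LabelVolume (empty dict when
    ``keep_volumes=False``) and ``index`` is a tidy DataFrame with one row
    per 2D slice record and one per 3D record.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if any(not (0.0 <= d <= 1.0) for d in dsc_grid):
        raise ValueError("dsc_grid values must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    # modes that support graded calibration across most of the dice range
    cal_modes = ("dilate", "erode", "boundary_jitter", "translate")
    targets = variant_targets(n_variants, dsc_grid)
    segmentations: dict = {}
    rows = []
    for si, (params, img, gt_labels) in enumerate(cohort):
        for structure in structures:
            gt = gt_labels.structure_mask(structure)
            for v in range(n_variants):
                target = targets[v]
                mode = cal_modes[int(rng.integers(len(cal_modes)))]
                pseed = int(rng.integers(0, 2**31 - 1))
                if target <= 0.0:
                    spec = PerturbationSpec(mode="empty", severity=1.0, seed=pseed)
                else:
                    try:
                        spec = calibrate_severity(gt_labels, structure, target, mode, seed=pseed)
                    except ValueError:  # target below the mode's floor: take its worst
                        spec = PerturbationSpec(mode=mode, severity=1.0, seed=pseed)
                pert_labels = perturb_mask(gt_labels, spec, structure)
                pert = pert_labels.structure_mask(structure)
                if keep_volumes:
                    segmentations[(si, structure, v)] = pert_labels
                d3 = dsc(pert, gt)
                rows.append({
                    "subject": si, "structure": structure, "variant": v,
                    "level": "3D", "slice_index": -1, "actual_dsc": d3,
                    "mode": spec.mode, "severity": spec.severity,
                    "preset": params.preset, "empty_pair": False,
                })
                for rec in _slice_records(pert, gt):
                    rows.append({
                        "subject": si, "structure": structure, "variant": v,
                        "level": "2D", "slice_index": rec["slice_index"],
                        "actual_dsc": rec["actual_dsc"],
                        "mode": spec.mode, "severity": spec.severity,
                        "preset": params.preset, "empty_pair": rec["empty_pair"],
                    })
    index = pd.DataFrame(rows)
    return segmentations, index
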