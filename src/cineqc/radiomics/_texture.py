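"""Gray-level texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM).

All matrices follow the IBSI aggregation conventions: distance-1
neighbourhoods, symmetric co-occurrence, and angle averaging of per-direction
features (4 directions in 2D, 13 in 3D).  Inputs are a discretized integer
array ``disc`` with levels 1..Ng inside the ROI and 0 outside; level values
are absolute (anchored at intensity 0), so gray-level-weighted features are
comparable across masks of the same image.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = np.spacing(1.0)


def _directions(ndim: int) -> list[tuple[int, ...]]:
    """Unique distance-1 directions up to sign: 4 in 2D, 13 in 3D."""
    dirs = []
    for off in np.ndindex(*([3] * ndim)):
        d = tuple(int(o) - 1 for o in off)
        if all(v == 0 for v in d):
            continue
        if tuple(-v for v in d) in dirs:
            continue
        dirs.append(d)
    return dirs


def _shift_pairs(disc: np.ndarray, d: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (center, neighbour) level arrays for offset ``d`` (0 = outside)."""
    slc_a, slc_b = [], []
    for n, dv in zip(disc.shape, d):
        if dv == 0:
            slc_a.append(slice(0, n))
            slc_b.append(slice(0, n))
        elif dv > 0:
            slc_a.append(slice(0, n - dv))
            slc_b.append(slice(dv, n))
        else:
            slc_a.append(slice(-dv, n))
            slc_b.append(slice(0, n + dv))
    return disc[tuple(slc_a)], disc[tuple(slc_b)]


# ---------------------------------------------------------------------------
# GLCM

GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)


def _glcm_single(P: np.ndarray, g: np.ndarray) -> dict[str, float]:
    """Features of one normalised symmetric co-occurrence matrix.

    ``g`` holds the gray values of the matrix rows/columns.
    """
    Ng = len(g)
    i = g[:, None].astype(float)
    j = g[None, :].astype(float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float((px * g).sum())
    uy = float((py * g).sum())
    sx = float(np.sqrt((px * (g - ux) ** 2).sum()))
    sy = float(np.sqrt((py * (g - uy) ** 2).sum()))

    diff = np.abs(i - j)
    ssum = i + j
    # p_{x-y} and p_{x+y} over realized values
    kd = np.unique(diff)
    p_dm = np.array([P[diff == k].sum() for k in kd])
    ks = np.unique(ssum)
    p_sm = np.array([P[ssum == k].sum() for k in ks])

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((P * i * j).sum())
    out["JointAverage"] = ux
    cdev = i + j - ux - uy
    out["ClusterProminence"] = float((P * cdev ** 4).sum())
    out["ClusterShade"] = float((P * cdev ** 3).sum())
    out["ClusterTendency"] = float((P * cdev ** 2).sum())
    out["Contrast"] = float((P * (i - j) ** 2).sum())
    if sx * sy > 0:
        out["Correlation"] = float(((P * i * j).sum() - ux * uy) / (sx * sy))
    else:
        out["Correlation"] = 1.0  # single gray level: perfect (degenerate) correlation
    da = float((p_dm * kd).sum())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = float(-(p_dm * np.log2(p_dm + _EPS)).sum())
    out["DifferenceVariance"] = float((p_dm * (kd - da) ** 2).sum())
    out["JointEnergy"] = float((P ** 2).sum())
    hxy = float(-(P * np.log2(P + _EPS)).sum())
    out["JointEntropy"] = hxy
    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())
    pxy = px[:, None] * py[None, :]
    hxy1 = float(-(P * np.log2(pxy + _EPS)).sum())
    hxy2 = float(-(pxy * np.log2(pxy + _EPS)).sum())
    denom = max(hx, hy)
    out["Imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    out["Imc2"] = float(np.sqrt(max(arg, 0.0)))
    out["Idm"] = float((P / (1.0 + (i - j) ** 2)).sum())
    out["Idmn"] = float((P / (1.0 + ((i - j) / Ng) ** 2)).sum())
    out["Id"] = float((P / (1.0 + diff)).sum())
    out["Idn"] = float((P / (1.0 + diff / Ng)).sum())
    off = diff > 0
    out["InverseVariance"] = float((P[off] / diff[off] ** 2).sum()) if off.any() else 0.0
    out["MaximumProbability"] = float(P.max())
    out["SumAverage"] = float((p_sm * ks).sum())
    out["SumEntropy"] = float(-(p_sm * np.log2(p_sm + _EPS)).sum())
    out["SumSquares"] = float((P * (i - ux) ** 2).sum())
    if Ng == 1:
        out["MCC"] = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            Q = ((P[:, None, :] * P[None, :, :]) /
                 (px[:, None, None] * py[None, None, :] + _EPS)).sum(axis=2)
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        out["MCC"] = float(np.sqrt(max(ev[-2], 0.0))) if len(ev) > 1 else 1.0
    return out


def glcm_features(disc: np.ndarray) -> dict[str, float]:
    """Angle-averaged co-occurrence features of a discretized ROI."""
    levels = np.unique(disc[disc > 0])
    lut = np.zeros(int(levels.max()) + 1, dtype=np.intp)
    lut[levels] = np.arange(len(levels))
    per_dir: list[dict[str, float]] = []
    for d in _directions(disc.ndim):
        a, b = _shift_pairs(disc, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        ia, ib = lut[a[valid]], lut[b[valid]]
        C = np.zeros((len(levels), len(levels)), dtype=np.float64)
        np.add.at(C, (ia, ib), 1.0)
        C = C + C.T  # symmetric co-occurrence
        per_dir.append(_glcm_single(C / C.sum(), levels.astype(float)))
    if not per_dir:  # single-pixel ROI: no pairs in any direction
        per_dir = [_glcm_single(np.ones((1, 1)), levels.astype(float))]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRLM

GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def _sheared_lines(disc: np.ndarray, d: tuple[int, ...]) -> np.ndarray:
    """Concatenate all grid lines along direction ``d`` with 0 separators.

    The array is sheared so that ``d`` becomes the leading axis; zero fill
    breaks runs exactly where the ROI (or the grid) ends.
    """
    nz = [k for k, v in enumerate(d) if v != 0]
    lead = nz[0]
    arr = np.moveaxis(disc, lead, 0)
    dvec = list(d)
    dvec.insert(0, dvec.pop(lead))
    if arr.ndim == 1 or all(v == 0 for v in dvec[1:]):
        lines = arr.reshape(arr.shape[0], -1).T if arr.ndim > 1 else arr[None, :]
    else:
        n0 = arr.shape[0]
        rest = arr.shape[1:]
        canvas_shape = (n0,) + tuple(r + (n0 - 1) * abs(v) for r, v in zip(rest, dvec[1:]))
        canvas = np.zeros(canvas_shape, dtype=disc.dtype)
        for k in range(n0):
            offs = tuple(k * v if v >= 0 else (n0 - 1 - k) * (-v) for v in dvec[1:])
            sl = tuple(slice(o, o + r) for o, r in zip(offs, rest))
            canvas[(k,) + sl] = arr[k]
        lines = canvas.reshape(n0, -1).T
    sep = np.zeros((lines.shape[0], 1), dtype=disc.dtype)
    return np.hstack([lines, sep]).ravel()


def _run_lengths(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(value, length) of each maximal run of equal nonzero values."""
    if seq.size == 0:
        return np.array([], dtype=seq.dtype), np.array([], dtype=np.intp)
    change = np.flatnonzero(np.diff(seq)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [seq.size]])
    vals = seq[starts]
    keep = vals > 0
    return vals[keep], (ends - starts)[keep]


def _glrlm_single(vals: np.ndarray, lens: np.ndarray, n_roi: int) -> dict[str, float]:
    nr = float(len(vals))
    g = vals.astype(float)
    l = lens.astype(float)
    p = 1.0 / nr
    out: dict[str, float] = {}
    out["ShortRunEmphasis"] = float((1.0 / l ** 2).sum() / nr)
    out["LongRunEmphasis"] = float((l ** 2).sum() / nr)
    gl_counts = {}
    for gv in np.unique(vals):
        gl_counts[gv] = float((vals == gv).sum())
    gln = sum(c ** 2 for c in gl_counts.values())
    out["GrayLevelNonUniformity"] = gln / nr
    out["GrayLevelNonUniformityNormalized"] = gln / nr ** 2
    rl_counts = {}
    for lv in np.unique(lens):
        rl_counts[lv] = float((lens == lv).sum())
    rln = sum(c ** 2 for c in rl_counts.values())
    out["RunLengthNonUniformity"] = rln / nr
    out["RunLengthNonUniformityNormalized"] = rln / nr ** 2
    out["RunPercentage"] = nr / float(n_roi)
    mu_g = g.mean()
    out["GrayLevelVariance"] = float(((g - mu_g) ** 2).mean())
    mu_l = l.mean()
    out["RunVariance"] = float(((l - mu_l) ** 2).mean())
    # entropy over the joint (gray, length) histogram
    joint: dict[tuple, float] = {}
    for gv, lv in zip(vals, lens):
        joint[(gv, lv)] = joint.get((gv, lv), 0.0) + p
    out["RunEntropy"] = float(-sum(q * np.log2(q + _EPS) for q in joint.values()))
    out["LowGrayLevelRunEmphasis"] = float((1.0 / g ** 2).sum() / nr)
    out["HighGrayLevelRunEmphasis"] = float((g ** 2).sum() / nr)
    out["ShortRunLowGrayLevelEmphasis"] = float((1.0 / (g ** 2 * l ** 2)).sum() / nr)
    out["ShortRunHighGrayLevelEmphasis"] = float((g ** 2 / l ** 2).sum() / nr)
    out["LongRunLowGrayLevelEmphasis"] = float((l ** 2 / g ** 2).sum() / nr)
    out["LongRunHighGrayLevelEmphasis"] = float((l ** 2 * g ** 2).sum() / nr)
    return out


def glrlm_features(disc: np.ndarray) -> dict[str, float]:
    """Angle-averaged run-length features of a discretized ROI."""
    n_roi = int((disc > 0).sum())
    per_dir = []
    for d in _directions(disc.ndim):
        vals, lens = _run_lengths(_sheared_lines(disc, d))
        if len(vals) == 0:
            continue
        per_dir.append(_glrlm_single(vals, lens, n_roi))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM

GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)


def glszm_features(disc: np.ndarray) -> dict[str, float]:
    """Size-zone features: zones are fully-connected same-level components."""
    structure = ndimage.generate_binary_structure(disc.ndim, disc.ndim)
    zone_vals: list[int] = []
    zone_sizes: list[int] = []
    for gv in np.unique(disc[disc > 0]):
        lab, nlab = ndimage.label(disc == gv, structure=structure)
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            zone_vals.extend([int(gv)] * nlab)
            zone_sizes.extend(int(s) for s in sizes)
    g = np.array(zone_vals, dtype=float)
    s = np.array(zone_sizes, dtype=float)
    nz = float(len(g))
    n_roi = int((disc > 0).sum())
    out: dict[str, float] = {}
    out["SmallAreaEmphasis"] = float((1.0 / s ** 2).sum() / nz)
    out["LargeAreaEmphasis"] = float((s ** 2).sum() / nz)
    gln = sum(float((g == gv).sum()) ** 2 for gv in np.unique(g))
    out["GrayLevelNonUniformity"] = gln / nz
    out["GrayLevelNonUniformityNormalized"] = gln / nz ** 2
    szn = sum(float((s == sv).sum()) ** 2 for sv in np.unique(s))
    out["SizeZoneNonUniformity"] = szn / nz
    out["SizeZoneNonUniformityNormalized"] = szn / nz ** 2
    out["ZonePercentage"] = nz / float(n_roi)
    out["GrayLevelVariance"] = float(((g - g.mean()) ** 2).mean())
    out["ZoneVariance"] = float(((s - s.mean()) ** 2).mean())
    joint: dict[tuple, float] = {}
    p = 1.0 / nz
    for gv, sv in zip(zone_vals, zone_sizes):
        joint[(gv, sv)] = joint.get((gv, sv), 0.0) + p
    out["ZoneEntropy"] = float(-sum(q * np.log2(q + _EPS) for q in joint.values()))
    out["LowGrayLevelZoneEmphasis"] = float((1.0 / g ** 2).sum() / nz)
    out["HighGrayLevelZoneEmphasis"] = float((g ** 2).sum() / nz)
    out["SmallAreaLowGrayLevelEmphasis"] = float((1.0 / (g ** 2 * s ** 2)).sum() / nz)
    out["SmallAreaHighGrayLevelEmphasis"] = float((g ** 2 / s ** 2).sum() / nz)
    out["LargeAreaLowGrayLevelEmphasis"] = float((s ** 2 / g ** 2).sum() / nz)
    out["LargeAreaHighGrayLevelEmphasis"] = float((s ** 2 * g ** 2).sum() / nz)
    return out


# ---------------------------------------------------------------------------
# GLDM

GLDM_FEATURES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis", "GrayLevelNonUniformity",
    "DependenceNonUniformity", "DependenceNonUniformityNormalized",
    "GrayLevelVariance", "DependenceVariance", "DependenceEntropy",
    "LowGrayLevelEmphasis", "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LargeDependenceHighGrayLevelEmphasis",
)


def _neighbour_offsets(ndim: int) -> list[tuple[int, ...]]:
    offs = []
    for off in np.ndindex(*([3] * ndim)):
        d = tuple(int(o) - 1 for o in off)
        if any(d):
            offs.append(d)
    return offs


def gldm_features(disc: np.ndarray, alpha: int = 0) -> dict[str, float]:
    """Dependence features: a neighbour is dependent when |Δlevel| <= alpha.

    The dependence size of a voxel is 1 + (number of dependent neighbours),
    so sizes start at 1 and size-weighted emphases are always defined.
    """
    roi = disc > 0
    dep = np.zeros(disc.shape, dtype=np.intp)
    for d in _neighbour_offsets(disc.ndim):
        a, b = _shift_pairs(disc, d)
        ok = (a > 0) & (b > 0) & (np.abs(a.astype(int) - b.astype(int)) <= alpha)
        slc = tuple(slice(0, n - dv) if dv > 0 else slice(-dv, n)
                    for n, dv in zip(disc.shape, d))
        dep[slc] += ok
    g = disc[roi].astype(float)
    j = dep[roi].astype(float) + 1.0
    nd = float(g.size)
    out: dict[str, float] = {}
    out["SmallDependenceEmphasis"] = float((1.0 / j ** 2).sum() / nd)
    out["LargeDependenceEmphasis"] = float((j ** 2).sum() / nd)
    gln = sum(float((g == gv).sum()) ** 2 for gv in np.unique(g))
    out["GrayLevelNonUniformity"] = gln / nd
    dn = sum(float((j == jv).sum()) ** 2 for jv in np.unique(j))
    out["DependenceNonUniformity"] = dn / nd
    out["DependenceNonUniformityNormalized"] = dn / nd ** 2
    out["GrayLevelVariance"] = float(((g - g.mean()) ** 2).mean())
    out["DependenceVariance"] = float(((j - j.mean()) ** 2).mean())
    joint: dict[tuple, float] = {}
    p = 1.0 / nd
    for gv, jv in zip(g, j):
        joint[(gv, jv)] = joint.get((gv, jv), 0.0) + p
    out["DependenceEntropy"] = float(-sum(q * np.log2(q + _EPS) for q in joint.values()))
    out["LowGrayLevelEmphasis"] = float((1.0 / g ** 2).sum() / nd)
    out["HighGrayLevelEmphasis"] = float((g ** 2).sum() / nd)
    out["SmallDependenceLowGrayLevelEmphasis"] = float((1.0 / (g ** 2 * j ** 2)).sum() / nd)
    out["SmallDependenceHighGrayLevelEmphasis"] = float((g ** 2 / j ** 2).sum() / nd)
    out["LargeDependenceLowGrayLevelEmphasis"] = float((j ** 2 / g ** 2).sum() / nd)
    out["LargeDependenceHighGrayLevelEmphasis"] = float((j ** 2 * g ** 2).sum() / nd)
    return out


# ---------------------------------------------------------------------------
# NGTDM

NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def ngtdm_features(disc: np.ndarray) -> dict[str, float]:
    """Neighbourhood gray-tone difference features (Amadasun & King)."""
    roi = disc > 0
    nb_sum = np.zeros(disc.shape, dtype=np.float64)
    nb_cnt = np.zeros(disc.shape, dtype=np.float64)
    for d in _neighbour_offsets(disc.ndim):
        a, b = _shift_pairs(disc, d)
        ok = (a > 0) & (b > 0)
        slc = tuple(slice(0, n - dv) if dv > 0 else slice(-dv, n)
                    for n, dv in zip(disc.shape, d))
        nb_sum[slc] += np.where(ok, b, 0)
        nb_cnt[slc] += ok
    valid = roi & (nb_cnt > 0)
    levels = np.unique(disc[roi])
    nvp = float(valid.sum())
    g_arr, p_arr, s_arr = [], [], []
    for gv in levels:
        sel = valid & (disc == gv)
        n_i = float(sel.sum())
        if n_i == 0:
            continue
        abar = nb_sum[sel] / nb_cnt[sel]
        g_arr.append(float(gv))
        p_arr.append(n_i / nvp)
        s_arr.append(float(np.abs(gv - abar).sum()))
    g = np.array(g_arr)
    p = np.array(p_arr)
    s = np.array(s_arr)
    ngp = len(g)
    out: dict[str, float] = {}
    ps = float((p * s).sum())
    out["Coarseness"] = float(1.0 / ps) if ps > 0 else 1e6
    if ngp > 1:
        gi = g[:, None]
        gj = g[None, :]
        pi = p[:, None]
        pj = p[None, :]
        out["Contrast"] = float((pi * pj * (gi - gj) ** 2).sum() / (ngp * (ngp - 1))
                                * s.sum() / nvp)
        denom = float(np.abs(gi * pi - gj * pj).sum())
        out["Busyness"] = float(ps / denom) if denom > 0 else 0.0
        out["Complexity"] = float((np.abs(gi - gj) * (pi * s[:, None] + pj * s[None, :])
                                   / (pi + pj)).sum() / nvp)
        ssum = float(s.sum())
        out["Strength"] = float(((pi + pj) * (gi - gj) ** 2).sum() / ssum) if ssum > 0 else 0.0
    else:
        out["Contrast"] = 0.0
        out["Busyness"] = 0.0
        out["Complexity"] = 0.0
        out["Strength"] = 0.0
    return out
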