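"""IBSI-aligned radiomic feature extraction from an (image, mask) pair.

Features fall into three families:

* geometry — voxel-counting volume, face-counted surface area, sphericity,
  maximum 3-D diameter (largest pairwise distance between surface-voxel
  centres), and PCA elongation;
* intensity first-order — moments, percentiles and fixed-bin-width
  discretised entropy of the voxel intensities;
* texture — grey-level co-occurrence (GLCM) and grey-level run-length
  (GLRLM) statistics, computed symmetrically over the 13 unique 3-D
  directions and averaged.

Discretisation is fixed bin width (default 25 on the 0-255 preprocessed
scale), anchored at the ROI minimum so an intensity shift relabels nothing.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .imaging import ImageVolume, MaskVolume

__all__ = [
    "OFFSETS_3D",
    "extract_features",
    "fuse_phases",
    "quantize",
    "glcm_matrix",
    "glcm_features",
    "glrlm_features",
]

# The 13 unique 3-D directions (first nonzero component positive); with the
# symmetric convention these cover all 26 neighbours.
OFFSETS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


def quantize(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Fixed-bin-width discretisation anchored at the minimum.

    Returns integer grey levels in ``0..n_levels-1``. A constant region
    maps to a single level.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be > 0, got {bin_width}")
    v = np.asarray(values, dtype=np.float64)
    levels = np.floor((v - v.min()) / bin_width).astype(np.int64)
    return levels, int(levels.max()) + 1


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(
    levels_volume: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    offset: tuple[int, int, int],
) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one offset (not normalised)."""
    a_sl, b_sl = [], []
    for d in offset:
        if d > 0:
            a_sl.append(slice(0, -d) if d else slice(None))
            b_sl.append(slice(d, None))
        elif d < 0:
            a_sl.append(slice(-d, None))
            b_sl.append(slice(0, d))
        else:
            a_sl.append(slice(None))
            b_sl.append(slice(None))
    a_sl, b_sl = tuple(a_sl), tuple(b_sl)
    valid = mask[a_sl] & mask[b_sl]
    ga = levels_volume[a_sl][valid]
    gb = levels_volume[b_sl][valid]
    counts = np.bincount(ga * n_levels + gb, minlength=n_levels * n_levels)
    mat = counts.reshape(n_levels, n_levels).astype(np.float64)
    return mat + mat.T


def _glcm_props(p: np.ndarray) -> dict[str, float]:
    """Contrast, correlation, joint entropy, homogeneity of one normalised GLCM."""
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sigma2 > 1e-12:
        correlation = float((((ii - mu) * (jj - mu) * p).sum()) / sigma2)
    else:
        correlation = 1.0  # constant region: degenerate, perfectly correlated
    nz = p[p > 0]
    joint_entropy = float(-(nz * np.log2(nz)).sum())
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    return {
        "contrast": contrast,
        "correlation": correlation,
        "joint_entropy": joint_entropy,
        "homogeneity": homogeneity,
    }


def glcm_features(
    levels_volume: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """Direction-averaged GLCM features over the 13 unique 3-D offsets."""
    acc: dict[str, list[float]] = {}
    for off in OFFSETS_3D:
        mat = glcm_matrix(levels_volume, mask, n_levels, off)
        total = mat.sum()
        if total == 0:
            continue
        for k, v in _glcm_props(mat / total).items():
            acc.setdefault(k, []).append(v)
    if not acc:
        return {k: np.nan for k in ("contrast", "correlation", "joint_entropy", "homogeneity")}
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM


def _runs_one_direction(
    levels_volume: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Grey level and length of every maximal run along one direction."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    lv = levels_volume[mask]
    d = np.asarray(offset)
    # Parameterise each line by t = position along the first nonzero axis of
    # the direction; (i,j,k) - t*d is constant on a line.
    axis = int(np.nonzero(d)[0][0])
    t = idx[:, axis] // d[axis]
    line_id = idx - t[:, None] * d
    order = np.lexsort((t, line_id[:, 2], line_id[:, 1], line_id[:, 0]))
    t_s = t[order]
    lid_s = line_id[order]
    lv_s = lv[order]
    same_line = np.all(lid_s[1:] == lid_s[:-1], axis=1)
    contiguous = t_s[1:] == t_s[:-1] + 1
    same_level = lv_s[1:] == lv_s[:-1]
    brk = ~(same_line & contiguous & same_level)
    run_id = np.concatenate(([0], np.cumsum(brk)))
    lengths = np.bincount(run_id)
    starts = np.concatenate(([0], np.nonzero(brk)[0] + 1))
    return lv_s[starts], lengths


def glrlm_features(
    levels_volume: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """Direction-averaged run-length features (SRE, LRE, GLN, RLN)."""
    feats = {"sre": [], "lre": [], "gln": [], "rln": []}
    for off in OFFSETS_3D:
        glv, length = _runs_one_direction(levels_volume, mask, off)
        n_r = length.size
        if n_r == 0:
            continue
        lf = length.astype(np.float64)
        feats["sre"].append(float(np.sum(1.0 / lf**2) / n_r))
        feats["lre"].append(float(np.sum(lf**2) / n_r))
        gl_counts = np.bincount(glv, minlength=n_levels).astype(np.float64)
        feats["gln"].append(float(np.sum(gl_counts**2) / n_r))
        rl_counts = np.bincount(length).astype(np.float64)
        feats["rln"].append(float(np.sum(rl_counts**2) / n_r))
    if not feats["sre"]:
        return {k: np.nan for k in feats}
    return {k: float(np.mean(v)) for k, v in feats.items()}


# ---------------------------------------------------------------------------
# geometry + first-order


def _surface_area_mm2(mask: np.ndarray, spacing) -> float:
    """Face-counted surface area: every exposed voxel face contributes."""
    sx, sy, sz = spacing
    face_areas = (sy * sz, sx * sz, sx * sy)
    padded = np.pad(mask, 1)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        area += np.count_nonzero(diff) * fa
    return float(area)


def _max_diameter_mm(coords_mm: np.ndarray) -> float:
    if len(coords_mm) < 2:
        return 0.0
    pts = coords_mm
    if len(pts) > 10 and np.linalg.matrix_rank(pts - pts.mean(0)) == 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    return float(pdist(pts).max())


def _geometry(mask: MaskVolume) -> dict[str, float]:
    sp = np.asarray(mask.spacing)
    idx = np.argwhere(mask.values)
    n = len(idx)
    voxel_vol = float(np.prod(sp))
    volume = n * voxel_vol
    area = _surface_area_mm2(mask.values, mask.spacing)
    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
    # the maximum diameter is attained between surface voxels
    interior = ndimage.binary_erosion(mask.values)
    surface = mask.values & ~interior
    coords_mm = np.argwhere(surface) * sp if surface.any() else idx * sp
    diameter = _max_diameter_mm(coords_mm)
    coords_mm = idx * sp
    if n > 1:
        cov = np.cov(coords_mm.T)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        elongation = float(np.sqrt(max(eig[1], 0.0) / eig[0])) if eig[0] > 0 else 1.0
    else:
        elongation = 1.0
    return {
        "shape.volume_mm3": volume,
        "shape.surface_area_mm2": area,
        "shape.sphericity": sphericity,
        "shape.max_diameter_mm": diameter,
        "shape.elongation": elongation,
    }


def _first_order(values: np.ndarray, bin_width: float) -> dict[str, float]:
    v = np.asarray(values, dtype=np.float64)
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    if sd > 1e-12:
        skew = float(np.mean(((v - mean) / sd) ** 3))
        kurt = float(np.mean(((v - mean) / sd) ** 4))
    else:
        skew, kurt = 0.0, 0.0  # degenerate-by-convention
    levels, _ = quantize(v, bin_width)
    p = np.bincount(levels) / levels.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    p10, p90 = np.percentile(v, [10, 90])
    q1, q3 = np.percentile(v, [25, 75])
    return {
        "firstorder.mean": mean,
        "firstorder.median": float(np.median(v)),
        "firstorder.sd": sd,
        "firstorder.energy": float(np.sum(v**2)),
        "firstorder.entropy": entropy,
        "firstorder.skewness": skew,
        "firstorder.kurtosis": kurt,
        "firstorder.p10": float(p10),
        "firstorder.p90": float(p90),
        "firstorder.iqr": float(q3 - q1),
    }


_TEXTURE_NAMES = (
    "glcm.contrast", "glcm.correlation", "glcm.joint_entropy", "glcm.homogeneity",
    "glrlm.sre", "glrlm.lre", "glrlm.gln", "glrlm.rln",
)
_FIRSTORDER_NAMES = (
    "firstorder.mean", "firstorder.median", "firstorder.sd", "firstorder.energy",
    "firstorder.entropy", "firstorder.skewness", "firstorder.kurtosis",
    "firstorder.p10", "firstorder.p90", "firstorder.iqr",
)


def extract_features(
    image: ImageVolume, mask: MaskVolume, bin_width: float = 25.0
) -> dict[str, float]:
    """Extract the full geometry + first-order + texture feature vector.

    A single-voxel mask yields geometry only (intensity and texture marked
    missing); texture needs at least one co-occurring voxel pair.
    """
    if mask.voxel_count() == 0:
        raise ValueError("cannot extract features from an empty mask")
    if image.shape != mask.shape:
        raise ValueError(
            f"image and mask shapes differ: {image.shape} vs {mask.shape}"
        )
    feats = _geometry(mask)
    if mask.voxel_count() == 1:
        for name in _FIRSTORDER_NAMES + _TEXTURE_NAMES:
            feats[name] = np.nan
        return feats
    roi_values = image.values[mask.values]
    feats.update(_first_order(roi_values, bin_width))
    # crop to the ROI bounding box: texture only sees in-mask pairs anyway
    idx = np.argwhere(mask.values)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_mask = mask.values[sl]
    levels_volume = np.zeros(sub_mask.shape, dtype=np.int64)
    levels_sub, n_levels = quantize(image.values[sl][sub_mask], bin_width)
    levels_volume[sub_mask] = levels_sub
    feats.update(
        {f"glcm.{k}": v
         for k, v in glcm_features(levels_volume, sub_mask, n_levels).items()}
    )
    feats.update(
        {f"glrlm.{k}": v
         for k, v in glrlm_features(levels_volume, sub_mask, n_levels).items()}
    )
    return feats


def fuse_phases(pre: dict[str, float], post: dict[str, float]) -> dict[str, float]:
    """Concatenate pre- and post-ablation feature vectors with phase prefixes."""
    fused: dict[str, float] = {}
    for prefix, vec in (("pre", pre), ("post", post)):
        for name, value in vec.items():
            key = f"{prefix}.{name}"
            if key in fused:
                raise ValueError(f"duplicate fused feature name: {key}")
            fused[key] = value
    return fused
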