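"""Habitat construction: block-level local features, Calinski-Harabasz
cluster-number selection, and canonical K-means habitat maps.

A lesion's region of interest is tiled with non-overlapping 3x3x3 voxel
blocks (on the 1 mm preprocessed grid). Each block with at least 50% of its
voxels inside the ROI contributes one 77-dimensional local feature vector:

* 16 first-order statistics of the block intensities;
* histogram entropy and uniformity at two bin settings (8 and 16 bins over
  the 0-255 scale) — 4 values;
* normalised local energy (sum of squared intensities / 255^2) — 1 value;
* 14 Haralick co-occurrence statistics x 2 grey-level settings (8 and 16
  levels) x 2 direction aggregations (mean and range over the 13 unique 3-D
  directions) — 56 values.

K-means (k-means++ init, fixed seed) clusters the per-lesion standardised
block vectors; the cluster count is chosen by maximising the
Calinski-Harabasz score over a small range, and labels are renumbered in
ascending order of mean block intensity so habitat 1 is always the darkest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .imaging import ImageVolume, MaskVolume
from .radiomics import OFFSETS_3D, extract_features

__all__ = [
    "BLOCK_FEATURE_NAMES",
    "BlockFeatureSet",
    "HabitatMap",
    "block_features",
    "ch_score",
    "select_k",
    "cluster_habitats",
    "habitat_features",
]

BLOCK = 3  # block edge length in voxels (1 mm grid)
_MIN_ROI_FRACTION = 0.5

_HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "diff_variance", "diff_entropy", "imc1", "imc2", "max_prob",
)


def _block_feature_names() -> tuple[str, ...]:
    names = [
        "fo.mean", "fo.sd", "fo.var", "fo.median", "fo.min", "fo.max",
        "fo.range", "fo.p10", "fo.p25", "fo.p75", "fo.p90", "fo.iqr",
        "fo.skewness", "fo.kurtosis", "fo.energy", "fo.rms",
    ]
    for nbins in (8, 16):
        names += [f"hist{nbins}.entropy", f"hist{nbins}.uniformity"]
    names += ["local.energy_norm"]
    for nlev in (8, 16):
        for agg in ("mean", "range"):
            names += [f"glcm{nlev}.{p}.{agg}" for p in _HARALICK_NAMES]
    return tuple(names)


BLOCK_FEATURE_NAMES: tuple[str, ...] = _block_feature_names()
assert len(BLOCK_FEATURE_NAMES) == 77


@dataclass(frozen=True)
class BlockFeatureSet:
    """Per-block local feature vectors over a lesion ROI."""

    block_index: np.ndarray      # (n_blocks, 3) lattice coordinates
    vectors: np.ndarray          # (n_blocks, 77)
    feature_names: tuple[str, ...] = BLOCK_FEATURE_NAMES
    block_origin: tuple[int, int, int] = (0, 0, 0)  # voxel offset of block (0,0,0)
    mean_intensity: np.ndarray | None = None  # (n_blocks,) raw block means

    @property
    def n_blocks(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class HabitatMap:
    """Integer habitat labels (1..K) over a lesion ROI; 0 = unlabelled."""

    labels: np.ndarray
    n_clusters: int

    def habitat_mask(self, label: int) -> np.ndarray:
        return self.labels == label


# ---------------------------------------------------------------------------
# Haralick statistics on a stack of normalised GLCMs


_SCATTER_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _scatter_matrices(L: int) -> tuple[np.ndarray, np.ndarray]:
    """(L^2, 2L-1) and (L^2, L) one-hot maps onto i+j and |i-j| indices."""
    if L not in _SCATTER_CACHE:
        i = np.arange(L)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        s_sum = np.zeros((L * L, 2 * L - 1))
        s_sum[np.arange(L * L), (ii + jj).ravel()] = 1.0
        s_diff = np.zeros((L * L, L))
        s_diff[np.arange(L * L), np.abs(ii - jj).ravel()] = 1.0
        _SCATTER_CACHE[L] = (s_sum, s_diff)
    return _SCATTER_CACHE[L]


def _haralick_stack(p_stack: np.ndarray) -> np.ndarray:
    """14 Haralick statistics for each GLCM in a (n_dir, L, L) stack."""
    n_dir, L, _ = p_stack.shape
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p_stack.sum(axis=2)                      # (n_dir, L)
    mu = (px * i).sum(axis=1)                     # (n_dir,)
    var = (px * (i[None, :] - mu[:, None]) ** 2).sum(axis=1)

    asm = (p_stack**2).sum(axis=(1, 2))
    contrast = (p_stack * (ii - jj) ** 2).sum(axis=(1, 2))
    num = (p_stack * (ii[None] - mu[:, None, None]) * (jj[None] - mu[:, None, None])).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        correlation = np.where(var > 1e-12, num / np.where(var > 1e-12, var, 1.0), 1.0)
    idm = (p_stack / (1.0 + (ii - jj) ** 2)).sum(axis=(1, 2))

    # p_{x+y} and p_{x-y} via cached scatter matrices (fast for small L)
    s_sum, s_diff = _scatter_matrices(L)
    flat = p_stack.reshape(n_dir, -1)
    pxy_sum = flat @ s_sum
    pxy_diff = flat @ s_diff
    k_sum = np.arange(2 * L - 1, dtype=np.float64)
    k_diff = np.arange(L, dtype=np.float64)
    sum_average = (pxy_sum * k_sum).sum(axis=1)
    sum_variance = (pxy_sum * (k_sum[None] - sum_average[:, None]) ** 2).sum(axis=1)

    def _ent(p):
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return -(p * lg).sum(axis=-1)

    sum_entropy = _ent(pxy_sum)
    entropy = _ent(p_stack.reshape(n_dir, -1))
    diff_mean = (pxy_diff * k_diff).sum(axis=1)
    diff_variance = (pxy_diff * (k_diff[None] - diff_mean[:, None]) ** 2).sum(axis=1)
    diff_entropy = _ent(pxy_diff)

    hx = _ent(px)
    py = p_stack.sum(axis=1)
    hy = _ent(py)
    pxpy = px[:, :, None] * py[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = -(p_stack * lg).sum(axis=(1, 2))
    hxy2 = -(pxpy * lg).sum(axis=(1, 2))
    denom = np.maximum(hx, hy)
    imc1 = np.where(denom > 1e-12, (entropy - hxy1) / np.where(denom > 1e-12, denom, 1.0), 0.0)
    arg = np.clip(1.0 - np.exp(-2.0 * (hxy2 - entropy)), 0.0, None)
    imc2 = np.sqrt(arg)
    max_prob = p_stack.max(axis=(1, 2))

    return np.stack([
        asm, contrast, correlation, var, idm, sum_average, sum_variance,
        sum_entropy, entropy, diff_variance, diff_entropy, imc1, imc2, max_prob,
    ], axis=1)  # (n_dir, 14)


def _block_pairs() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All in-block voxel index pairs for the 13 directions, flattened.

    Returns (direction id, flat index a, flat index b) arrays, precomputed
    once for the 3x3x3 lattice.
    """
    dirs, a_idx, b_idx = [], [], []
    for d_id, off in enumerate(OFFSETS_3D):
        for i in range(BLOCK):
            for j in range(BLOCK):
                for k in range(BLOCK):
                    i2, j2, k2 = i + off[0], j + off[1], k + off[2]
                    if 0 <= i2 < BLOCK and 0 <= j2 < BLOCK and 0 <= k2 < BLOCK:
                        dirs.append(d_id)
                        a_idx.append(i * 9 + j * 3 + k)
                        b_idx.append(i2 * 9 + j2 * 3 + k2)
    return (np.asarray(dirs), np.asarray(a_idx), np.asarray(b_idx))


_PAIR_DIR, _PAIR_A, _PAIR_B = _block_pairs()


def _block_occupancy(levels: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Flattened 3x3x3 grey-level occupancy (-1 outside ROI) for one block.

    ``levels`` are the ROI-wide discretised grey levels of the block's ROI
    voxels (see :func:`block_features`: bins span the lesion's own intensity
    range so in-tumour contrast is resolved).
    """
    occ = -np.ones(BLOCK**3, dtype=np.int64)
    occ[coords[:, 0] * 9 + coords[:, 1] * 3 + coords[:, 2]] = levels
    return occ


def _batch_glcm_feats(occ_all: np.ndarray, n_levels: int) -> np.ndarray:
    """Mean and range over 13 directions of the 14 Haralick stats, for every
    block at once; returns (n_blocks, 28)."""
    n_b = occ_all.shape[0]
    n_dir = len(OFFSETS_3D)
    ga = occ_all[:, _PAIR_A]
    gb = occ_all[:, _PAIR_B]
    ok = (ga >= 0) & (gb >= 0)
    L2 = n_levels * n_levels
    base = np.arange(n_b)[:, None] * n_dir + _PAIR_DIR[None, :]
    codes = base * L2 + ga * n_levels + gb
    flat = np.bincount(codes[ok], minlength=n_b * n_dir * L2).astype(np.float64)
    stack = flat.reshape(n_b * n_dir, n_levels, n_levels)
    stack = stack + stack.transpose(0, 2, 1)
    totals = stack.sum(axis=(1, 2), keepdims=True)
    stack = np.divide(stack, totals, out=stack, where=totals > 0)
    feats = _haralick_stack(stack).reshape(n_b, n_dir, 14)
    return np.concatenate([feats.mean(axis=1), np.ptp(feats, axis=1)], axis=1)


def _block_vector_base(values: np.ndarray, rmin: float, span: float) -> np.ndarray:
    return _base_feature_matrix(values[None, :].astype(np.float64), rmin, span)[0]


def _base_feature_matrix(V: np.ndarray, rmin: float, span: float) -> np.ndarray:
    """First-order + histogram + energy features for equal-size blocks.

    ``V`` is (n_blocks, n_voxels). Histogram bins span the lesion ROI's own
    intensity range: windowed lung CT concentrates tumour intensities in a
    narrow band of the 0-255 scale, so absolute bins would collapse every
    block to one bin.
    """
    V = V.astype(np.float64)
    g, c = V.shape
    mean = V.mean(axis=1)
    sd = V.std(axis=1)
    p10, p25, med, p75, p90 = np.percentile(V, [10, 25, 50, 75, 90], axis=1)
    mn = V.min(axis=1)
    mx = V.max(axis=1)
    safe_sd = np.where(sd > 1e-12, sd, 1.0)
    z = (V - mean[:, None]) / safe_sd[:, None]
    skew = np.where(sd > 1e-12, (z**3).mean(axis=1), 0.0)
    kurt = np.where(sd > 1e-12, (z**4).mean(axis=1), 0.0)
    energy = (V**2).sum(axis=1)
    rms = np.sqrt((V**2).mean(axis=1))
    cols = [mean, sd, sd**2, med, mn, mx, mx - mn,
            p10, p25, p75, p90, p75 - p25, skew, kurt, energy, rms]

    for nbins in (8, 16):
        idx = np.clip(((V - rmin) / span * nbins).astype(np.int64), 0, nbins - 1)
        offs = np.arange(g)[:, None] * nbins
        counts = np.bincount((idx + offs).ravel(), minlength=g * nbins)
        p = counts.reshape(g, nbins) / c
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        cols += [-(p * lg).sum(axis=1), (p**2).sum(axis=1)]
    cols += [((V / 255.0) ** 2).sum(axis=1)]
    return np.stack(cols, axis=1)


def block_features(image: ImageVolume, roi: MaskVolume) -> BlockFeatureSet:
    """Compute the 77-dimensional local feature vector for each 3x3x3 block.

    Blocks tile the ROI bounding box; only blocks with at least half their
    27 voxels inside the ROI are kept. Expects the preprocessed (1 mm,
    0-255) image.
    """
    if image.shape != roi.shape:
        raise ValueError("image and ROI grids are not aligned")
    idx = np.argwhere(roi.values)
    if idx.size == 0:
        raise ValueError("ROI is empty")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    if np.any(hi - lo < 1):
        raise ValueError("ROI smaller than one block")
    sub_img = image.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub_roi = roi.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    shape = sub_roi.shape
    n_blocks_axes = [int(np.ceil(s / BLOCK)) for s in shape]

    # ROI-range-adaptive grey levels, shared by all blocks of the lesion
    roi_vals = sub_img[sub_roi]
    rmin = float(roi_vals.min())
    span = max(float(roi_vals.max()) - rmin, 1e-9)
    lev8 = np.clip(((sub_img - rmin) / span * 8).astype(np.int64), 0, 7)
    lev16 = np.clip(((sub_img - rmin) / span * 16).astype(np.int64), 0, 15)

    indices, all_vals, occ8, occ16 = [], [], [], []
    for bi in range(n_blocks_axes[0]):
        for bj in range(n_blocks_axes[1]):
            for bk in range(n_blocks_axes[2]):
                sl = (
                    slice(bi * BLOCK, min((bi + 1) * BLOCK, shape[0])),
                    slice(bj * BLOCK, min((bj + 1) * BLOCK, shape[1])),
                    slice(bk * BLOCK, min((bk + 1) * BLOCK, shape[2])),
                )
                m = sub_roi[sl]
                if m.sum() < _MIN_ROI_FRACTION * BLOCK**3:
                    continue
                coords = np.argwhere(m)
                indices.append((bi, bj, bk))
                all_vals.append(sub_img[sl][m])
                occ8.append(_block_occupancy(lev8[sl][m], coords))
                occ16.append(_block_occupancy(lev16[sl][m], coords))
    if not indices:
        raise ValueError("ROI smaller than one block (no block reaches 50% coverage)")
    # first-order part vectorised per group of equal block voxel counts
    n_b = len(indices)
    base = np.empty((n_b, 21))
    sizes = np.array([len(v) for v in all_vals])
    for size in np.unique(sizes):
        rows = np.flatnonzero(sizes == size)
        V = np.stack([all_vals[r] for r in rows])
        base[rows] = _base_feature_matrix(V, rmin, span)
    means = np.array([v.mean() for v in all_vals])
    glcm = np.concatenate(
        [_batch_glcm_feats(np.asarray(occ8), 8),
         _batch_glcm_feats(np.asarray(occ16), 16)],
        axis=1,
    )
    vectors = np.concatenate([base, glcm], axis=1)
    return BlockFeatureSet(
        block_index=np.asarray(indices, dtype=np.int64),
        vectors=vectors,
        block_origin=tuple(int(x) for x in lo),
        mean_intensity=np.asarray(means, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# Calinski-Harabasz and K selection


def ch_score(vectors: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz score: [B/(k-1)] / [W/(n-k)].

    B is the between-cluster dispersion (size-weighted squared distances of
    centroids to the grand mean), W the pooled within-cluster sum of squared
    distances to centroids. W = 0 returns +inf.
    """
    X = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = uniq.size
    n = X.shape[0]
    if k < 2:
        raise ValueError(f"need at least 2 clusters, got {k}")
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for u in uniq:
        sub = X[labels == u]
        if sub.shape[0] == 0:
            raise ValueError(f"cluster {u} is empty")
        c = sub.mean(axis=0)
        B += sub.shape[0] * float(np.sum((c - grand) ** 2))
        W += float(np.sum((sub - c) ** 2))
    if W <= 1e-300:
        return np.inf
    return (B / (k - 1)) / (W / (n - k))


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (X - mu) / sd


def select_k(
    vectors: np.ndarray,
    k_range=range(2, 7),
    seed: int = 0,
    n_init: int = 5,
    standardize: bool = True,
) -> int:
    """Pick the cluster count maximising the Calinski-Harabasz score.

    Ties go to the smallest k. K-means is restarted ``n_init`` times per k
    with a fixed seed.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    X = np.asarray(vectors, dtype=np.float64)
    n = X.shape[0]
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"k range {ks} outside [2, n-1] with n={n}")
    Xs = _standardize(X) if standardize else X
    best_k, best_score = None, -np.inf
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(Xs)
        if np.unique(labels).size < 2:
            continue
        score = ch_score(Xs, labels)
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise ValueError("no k produced a valid clustering")
    return best_k


def cluster_habitats(
    features: BlockFeatureSet,
    n_clusters: int,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    roi: MaskVolume | None = None,
    n_init: int = 5,
) -> HabitatMap:
    """K-means the (per-lesion standardised) block vectors into habitats.

    Block labels are broadcast to member ROI voxels, and clusters are
    renumbered 1..K in ascending order of mean raw block intensity, so the
    canonical map does not depend on k-means' arbitrary label order. Voxels
    of blocks below the 50% coverage cut stay 0.
    """
    n_blocks = features.n_blocks
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > n_blocks:
        raise ValueError(f"n_clusters={n_clusters} exceeds n_blocks={n_blocks}")
    if n_clusters == 1:
        raw = np.ones(n_blocks, dtype=np.int64)
    else:
        Xs = _standardize(features.vectors)
        # fit on canonically sorted rows so the partition does not depend on
        # the (arbitrary) block enumeration order, then assign by nearest
        # centroid
        order = np.lexsort(Xs.T)
        km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=n_init,
                    random_state=seed)
        km.fit(Xs[order])
        raw = km.predict(Xs)
        # canonical order: ascending mean intensity
        intens = features.mean_intensity
        if intens is None:
            intens = features.vectors[:, 0]
        order = np.argsort([intens[raw == c].mean() for c in range(n_clusters)],
                           kind="stable")
        remap = np.empty(n_clusters, dtype=np.int64)
        remap[order] = np.arange(1, n_clusters + 1)
        raw = remap[raw]

    if shape is None and roi is not None:
        shape = roi.shape
    if shape is None:
        raise ValueError("provide shape or roi to build the label volume")
    labels = np.zeros(shape, dtype=np.int64)
    o = features.block_origin
    for (bi, bj, bk), lab in zip(features.block_index, raw):
        sl = (
            slice(o[0] + bi * BLOCK, min(o[0] + (bi + 1) * BLOCK, shape[0])),
            slice(o[1] + bj * BLOCK, min(o[1] + (bj + 1) * BLOCK, shape[1])),
            slice(o[2] + bk * BLOCK, min(o[2] + (bk + 1) * BLOCK, shape[2])),
        )
        if roi is not None:
            block_roi = roi.values[sl]
            labels[sl][block_roi] = lab
        else:
            labels[sl] = lab
    return HabitatMap(labels=labels, n_clusters=n_clusters)


def habitat_features(
    image: ImageVolume,
    hmap: HabitatMap,
    bin_width: float = 25.0,
    min_voxels: int = 8,
) -> dict[str, float]:
    """Radiomics per habitat plus the across-habitat mean of each feature.

    Habitats with fewer than ``min_voxels`` voxels are marked missing and
    excluded from the mean. Keys are ``habitat{k}.<feature>`` and
    ``habitatmean.<feature>``.
    """
    out: dict[str, float] = {}
    per_label: list[dict[str, float]] = []
    for lab in range(1, hmap.n_clusters + 1):
        m = hmap.habitat_mask(lab)
        if m.sum() < min_voxels:
            per_label.append({})
            continue
        mask = MaskVolume(m, spacing=image.spacing, origin=image.origin)
        per_label.append(extract_features(image, mask, bin_width=bin_width))
    names: list[str] = []
    for feats in per_label:
        for name in feats:
            if name not in names:
                names.append(name)
    for lab, feats in enumerate(per_label, start=1):
        for name in names:
            out[f"habitat{lab}.{name}"] = feats.get(name, np.nan)
    for name in names:
        vals = [f[name] for f in per_label if name in f and np.isfinite(f[name])]
        out[f"habitatmean.{name}"] = float(np.mean(vals)) if vals else np.nan
    return out
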