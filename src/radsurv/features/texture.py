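"""3-D texture features: GLCM (22), GLSZM (13), GLRLM (11), NGTDM (5).

Conventions (the dominant 3-D radiomics lineage):

* GLCM: distance-1 offsets over the 13 unique 3-D directions, symmetric
  accumulation, matrices normalized to probabilities; each feature is
  computed per direction and averaged over the 13 directions.
* GLSZM: zones are 26-connected components of equal gray level; a single
  direction-free matrix.
* GLRLM: maximal runs of equal gray level along each of the 13 directions,
  features averaged over directions.
* NGTDM: the neighborhood of a voxel is its 26-connected masked neighbors;
  voxels with no masked neighbor are excluded.

Logs are base 2 with 0*log(0) = 0.  All denominators carry an eps = 1e-12
guard; degenerate sentinels (constant region) are documented per feature.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = [
    "DIRECTIONS_13",
    "GLCM_FEATURES",
    "GLSZM_FEATURES",
    "GLRLM_FEATURES",
    "NGTDM_FEATURES",
    "glcm_matrix",
    "glcm_features",
    "glszm_matrix",
    "glszm_features",
    "glrlm_matrix",
    "glrlm_features",
    "ngtdm_table",
    "ngtdm_features",
]

EPS = 1e-12

#: The 13 unique direction offsets of a 3-D distance-1 neighborhood
#: (one representative per +/- pair, in (dx, dy, dz) order).
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz > 0) or (dz == 0 and dy > 0) or (dz == 0 and dy == 0 and dx > 0)
)
assert len(DIRECTIONS_13) == 13

GLCM_FEATURES = (
    "Autocorrelation",
    "Cluster_prominence",
    "Cluster_shade",
    "Cluster_tendency",
    "Contrast",
    "Correlation",
    "Difference_entropy",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity1",
    "Homogeneity2",
    "Information_measure_of_correlation1",
    "Information_measure_of_correlation2",
    "Inverse_difference_moment_normalized",
    "Inverse_difference_normalized",
    "Inverse_variance",
    "Maximum_probability",
    "Sum_average",
    "Sum_entropy",
    "Sum_variance",
    "Variance",
)

GLSZM_FEATURES = (
    "Short_zone_emphasis",
    "Large_zone_emphasis",
    "Gray_level_non_uniformity",
    "Zone_size_non_uniformity",
    "Zone_percentage",
    "Low_gray_level_zone_emphasis",
    "High_gray_level_zone_emphasis",
    "Small_zone_low_gray_level_emphasis",
    "Small_zone_high_gray_level_emphasis",
    "Large_zone_low_gray_level_emphasis",
    "Large_zone_high_gray_level_emphasis",
    "Gray_level_variance",
    "Zone_size_variance",
)

GLRLM_FEATURES = (
    "Short_run_emphasis",
    "Long_run_emphasis",
    "Gray_level_non_uniformity",
    "Run_length_non_uniformity",
    "Run_percentage",
    "Low_gray_level_run_emphasis",
    "High_gray_level_run_emphasis",
    "Short_run_low_gray_level_emphasis",
    "Short_run_high_gray_level_emphasis",
    "Long_run_low_gray_level_emphasis",
    "Long_run_high_gray_level_emphasis",
)

NGTDM_FEATURES = ("Contrast", "Busyness", "Complexity", "Coarseness", "Strength")


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(droi: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetric, probability-normalized co-occurrence matrix for one offset."""
    lvl, mask, ng = droi.level_map, droi.mask, droi.ng
    dx, dy, dz = direction

    def sl(d: int, n: int):
        if d == 0:
            return slice(0, n), slice(0, n)
        if d > 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    (ax0, bx0), (ay0, by0), (az0, bz0) = (
        sl(dx, lvl.shape[0]), sl(dy, lvl.shape[1]), sl(dz, lvl.shape[2]))
    a = lvl[ax0, ay0, az0]
    b = lvl[bx0, by0, bz0]
    valid = mask[ax0, ay0, az0] & mask[bx0, by0, bz0]
    i = a[valid] - 1
    j = b[valid] - 1
    mat = np.zeros((ng, ng), dtype=np.float64)
    np.add.at(mat, (i, j), 1.0)
    mat = mat + mat.T  # symmetric accumulation
    total = mat.sum()
    if total > 0:
        mat /= total
    return mat


def _glcm_features_one(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    # symmetric matrix: x and y marginals coincide
    mu_y, sigma_y = mu_x, sigma_x

    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    ksum = (ii + jj).astype(int)
    kdiff = np.abs(ii - jj).astype(int)
    p_sum = np.zeros(2 * ng + 1)
    np.add.at(p_sum, ksum.ravel(), p.ravel())
    p_diff = np.zeros(ng)
    np.add.at(p_diff, kdiff.ravel(), p.ravel())
    k_sum = np.arange(2 * ng + 1, dtype=np.float64)
    k_diff = np.arange(ng, dtype=np.float64)

    entropy = float(-_xlog2(p).sum())
    hx = float(-_xlog2(px).sum())
    pxy = np.outer(px, px)
    mask_nz = p > 0
    hxy1 = float(-(p[mask_nz] * np.log2(pxy[mask_nz] + EPS)).sum())
    hxy2 = float(-_xlog2(pxy).sum())

    if sigma_x * sigma_y > EPS:
        correlation = (float((ii * jj * p).sum()) - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        correlation = 1.0  # degenerate single-level matrix
    if hx > EPS:
        imc1 = (entropy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    sum_avg = float((k_sum * p_sum).sum())
    off_diag = kdiff > 0
    inv_var = float((p[off_diag] / kdiff[off_diag] ** 2).sum()) if off_diag.any() else 0.0

    mu = mu_x  # matrix mean gray level
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "Cluster_prominence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "Cluster_shade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "Cluster_tendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": float((kdiff**2 * p).sum()),
        "Correlation": correlation,
        "Difference_entropy": float(-_xlog2(p_diff).sum()),
        "Dissimilarity": float((kdiff * p).sum()),
        "Energy": float((p**2).sum()),
        "Entropy": entropy,
        "Homogeneity1": float((p / (1.0 + kdiff)).sum()),
        "Homogeneity2": float((p / (1.0 + kdiff**2)).sum()),
        "Information_measure_of_correlation1": imc1,
        "Information_measure_of_correlation2": imc2,
        "Inverse_difference_moment_normalized": float((p / (1.0 + (kdiff / ng) ** 2)).sum()),
        "Inverse_difference_normalized": float((p / (1.0 + kdiff / ng)).sum()),
        "Inverse_variance": inv_var,
        "Maximum_probability": float(p.max()),
        "Sum_average": sum_avg,
        "Sum_entropy": float(-_xlog2(p_sum).sum()),
        "Sum_variance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "Variance": float(((ii - mu) ** 2 * p).sum()),
    }


def glcm_features(droi: DiscretizedROI) -> dict[str, float]:
    """The 22 GLCM features, averaged over the 13 distance-1 directions."""
    acc: dict[str, float] = {k: 0.0 for k in GLCM_FEATURES}
    n_used = 0
    for d in DIRECTIONS_13:
        mat = glcm_matrix(droi, d)
        if mat.sum() == 0:  # no co-occurring pair along this offset
            continue
        feats = _glcm_features_one(mat, droi.ng)
        for k in GLCM_FEATURES:
            acc[k] += feats[k]
        n_used += 1
    if n_used == 0:
        raise ValueError("no voxel pairs in any direction (single-voxel ROI?)")
    return {k: v / n_used for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(droi: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix P[i, s]: zones of level i+1 with size s+1 (counts)."""
    lvl, mask, ng = droi.level_map, droi.mask, droi.ng
    zones: list[tuple[int, int]] = []
    max_size = 1
    for level in range(1, ng + 1):
        binary = (lvl == level) & mask
        if not binary.any():
            continue
        labels, _ = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            zones.append((level, int(s)))
            max_size = max(max_size, int(s))
    mat = np.zeros((ng, max_size), dtype=np.float64)
    for level, s in zones:
        mat[level - 1, s - 1] += 1.0
    return mat


def _szm_style_features(P: np.ndarray, n_voxels: int,
                        names: tuple[str, ...]) -> dict[str, float]:
    """Shared size-zone / run-length feature formulas on a counts matrix."""
    nz = P.sum()
    p = P / nz
    ng, ns = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    s = np.arange(1, ns + 1, dtype=np.float64)[None, :]
    pg = p.sum(axis=1)  # gray-level marginal
    ps = p.sum(axis=0)  # size/length marginal
    mu_i = float((np.arange(1, ng + 1) * pg).sum())
    mu_s = float((np.arange(1, ns + 1) * ps).sum())
    vals = {
        "small": float((p / s**2).sum()),
        "large": float((p * s**2).sum()),
        "gln": float((P.sum(axis=1) ** 2).sum() / nz),
        "szn": float((P.sum(axis=0) ** 2).sum() / nz),
        "pct": float(nz / n_voxels),
        "lgle": float((p / i**2).sum()),
        "hgle": float((p * i**2).sum()),
        "slge": float((p / (i**2 * s**2)).sum()),
        "shge": float((p * i**2 / s**2).sum()),
        "llge": float((p * s**2 / i**2).sum()),
        "lhge": float((p * i**2 * s**2).sum()),
        "glv": float((pg * (np.arange(1, ng + 1) - mu_i) ** 2).sum()),
        "ssv": float((ps * (np.arange(1, ns + 1) - mu_s) ** 2).sum()),
    }
    order = ["small", "large", "gln", "szn", "pct", "lgle", "hgle",
             "slge", "shge", "llge", "lhge", "glv", "ssv"]
    return dict(zip(names, (vals[k] for k in order[: len(names)])))


def glszm_features(droi: DiscretizedROI) -> dict[str, float]:
    """The 13 gray-level size-zone features (direction-free, 26-connected)."""
    P = glszm_matrix(droi)
    return _szm_style_features(P, droi.n_voxels, GLSZM_FEATURES)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _line_starts(shape: tuple[int, int, int], d: tuple[int, int, int]) -> np.ndarray:
    """Voxels p such that p - d lies outside the grid (starts of all lines)."""
    idx = np.indices(shape).reshape(3, -1).T
    prev = idx - np.asarray(d)
    outside = (
        (prev < 0) | (prev >= np.asarray(shape))
    ).any(axis=1)
    return idx[outside]


def glrlm_matrix(droi: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length matrix P[i, l]: runs of level i+1 with length l+1 (counts)."""
    lvl, mask, ng = droi.level_map, droi.mask, droi.ng
    shape = lvl.shape
    d = np.asarray(direction)
    runs: list[tuple[int, int]] = []
    max_len = 1
    for start in _line_starts(shape, direction):
        # walk the line; a run breaks on a level change or a mask gap
        n_steps = min(
            (shape[a] - 1 - start[a]) // d[a] if d[a] > 0
            else (start[a] // -d[a] if d[a] < 0 else np.iinfo(np.int64).max)
            for a in range(3)
        ) + 1
        coords = start[None, :] + np.arange(n_steps)[:, None] * d[None, :]
        line_lvl = lvl[coords[:, 0], coords[:, 1], coords[:, 2]]
        line_msk = mask[coords[:, 0], coords[:, 1], coords[:, 2]]
        cur_level, cur_len = 0, 0
        for v, m in zip(line_lvl, line_msk):
            if m and v == cur_level:
                cur_len += 1
            else:
                if cur_len:
                    runs.append((cur_level, cur_len))
                    max_len = max(max_len, cur_len)
                cur_level, cur_len = (int(v), 1) if m else (0, 0)
        if cur_len:
            runs.append((cur_level, cur_len))
            max_len = max(max_len, cur_len)
    mat = np.zeros((ng, max_len), dtype=np.float64)
    for level, length in runs:
        mat[level - 1, length - 1] += 1.0
    return mat


def glrlm_features(droi: DiscretizedROI) -> dict[str, float]:
    """The 11 run-length features, averaged over the 13 directions."""
    acc = {k: 0.0 for k in GLRLM_FEATURES}
    for d in DIRECTIONS_13:
        P = glrlm_matrix(droi, d)
        feats = _szm_style_features(P, droi.n_voxels, GLRLM_FEATURES)
        for k in GLRLM_FEATURES:
            acc[k] += feats[k]
    return {k: v / len(DIRECTIONS_13) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(droi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level occurrence counts n_i and summed deviations s_i.

    s_i sums |level - neighborhood mean| over masked voxels of level i that
    have at least one 26-connected masked neighbor; returns (n, s, N) with
    N the number of voxels entering the counts.
    """
    lvl, mask, ng = droi.level_map, droi.mask, droi.ng
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    m = mask.astype(np.float64)
    neigh_sum = ndimage.correlate(lvl * m, kernel, mode="constant")
    neigh_cnt = ndimage.correlate(m, kernel, mode="constant")
    valid = mask & (neigh_cnt > 0)
    a = neigh_sum[valid] / neigh_cnt[valid]
    levels = lvl[valid]
    n = np.zeros(ng)
    s = np.zeros(ng)
    np.add.at(n, levels - 1, 1.0)
    np.add.at(s, levels - 1, np.abs(levels - a))
    return n, s, int(valid.sum())


def ngtdm_features(droi: DiscretizedROI) -> dict[str, float]:
    """The 5 neighborhood gray-tone difference features.

    Constant-region sentinels: contrast/busyness/complexity/strength are 0
    and coarseness saturates at the 1/eps guard (1e12).
    """
    n, s, N = ngtdm_table(droi)
    if N == 0:
        raise ValueError("no voxel has a masked neighbor")
    p = n / N
    ng = len(p)
    i = np.arange(1, ng + 1, dtype=np.float64)
    nz = p > 0
    n_gp = int(nz.sum())

    coarseness = 1.0 / (EPS + float((p * s).sum()))

    if n_gp > 1:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        both = np.outer(nz, nz)
        contrast = (
            float((pi * pj * (ii - jj) ** 2)[both].sum()) / (n_gp * (n_gp - 1))
        ) * float(s.sum()) / N
        ipi = i * p
        denom_b = float(np.abs(ipi[nz, None] - ipi[None, nz]).sum())
        busyness = float((p * s).sum()) / denom_b if denom_b > EPS else 0.0
        # complexity: sum over i,j with p_i,p_j>0 of |i-j| (p_i s_i + p_j s_j)/(p_i+p_j) / N
        cmpx = (np.abs(ii - jj) * (pi * s[:, None] + pj * s[None, :]) /
                (pi + pj + EPS))
        complexity = float(cmpx[both].sum()) / N
        strength = (
            float(((pi + pj) * (ii - jj) ** 2)[both].sum()) / (EPS + float(s.sum()))
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Coarseness": coarseness,
        "Strength": strength,
    }
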