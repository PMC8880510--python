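"""3D texture matrices (GLRLM, GLSZM, GLCM, NGTDM) and their statistics.

All matrices aggregate the 13 unique 3D directions into a single merged
matrix (counts summed before statistics).  Runs and co-occurrences are
computed in voxel space; out-of-mask voxels break runs and pairs.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVolume

#: the 13 unique direction vectors of the 26-neighbourhood (one per +/- pair)
DIRECTIONS_13: list[tuple[int, int, int]] = [
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and d > (0, 0, 0)
]


def _take(a: np.ndarray, d: tuple[int, int, int], fill):
    """Array of a[v + d] with out-of-grid positions set to ``fill``."""
    out = np.full_like(a, fill)
    src = []
    dst = []
    for k, dk in enumerate(d):
        n = a.shape[k]
        if dk >= 0:
            dst.append(slice(0, n - dk))
            src.append(slice(dk, n))
        else:
            dst.append(slice(-dk, n))
            src.append(slice(0, n + dk))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _check(d: DiscretizedVolume):
    if d.mask.sum() < 2:
        raise ValueError("texture matrices need at least 2 in-mask voxels")


def glrlm(d: DiscretizedVolume) -> np.ndarray:
    """Grey-level run-length matrix r(i, j), 13 directions merged.

    Row i: grey level i+1; column j: run length j+1.  Maximal runs only;
    each in-mask voxel belongs to exactly one run per direction, so
    ``sum_j (j+1) * r[:, j]`` equals ``13 * n_voxels``.
    """
    _check(d)
    lev, mask = d.levels, d.mask
    max_run = max(lev.shape)
    R = np.zeros((d.n_levels, max_run), dtype=np.int64)
    for dd in DIRECTIONS_13:
        nxt_lev = _take(lev, dd, 0)
        nxt_mask = _take(mask, dd, False)
        link = mask & nxt_mask & (lev == nxt_lev)  # run continues v -> v+dd
        back = tuple(-x for x in dd)
        prev_link = _take(link, back, False)  # run continues (v-dd) -> v
        starts = mask & ~prev_link
        # chain length beyond v: c[v] = link[v] ? c[v+dd] + 1 : 0
        c = np.zeros(lev.shape, dtype=np.int32)
        for _ in range(max_run):
            c_new = np.where(link, _take(c, dd, 0) + 1, 0)
            if np.array_equal(c_new, c):
                break
            c = c_new
        lengths = c[starts] + 1
        np.add.at(R, (lev[starts] - 1, lengths - 1), 1)
    return R


def glszm(d: DiscretizedVolume) -> np.ndarray:
    """Grey-level size-zone matrix (zones = 26-connected equal-level
    components); row i: level i+1, column j: zone size j+1."""
    _check(d)
    structure = np.ones((3, 3, 3), dtype=int)
    zones = []
    for g in range(1, d.n_levels + 1):
        binary = (d.levels == g) & d.mask
        if not binary.any():
            continue
        lab, n = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    Z = np.zeros((d.n_levels, max_size), dtype=np.int64)
    for g, s in zones:
        Z[g - 1, s - 1] += 1
    return Z


def glcm(d: DiscretizedVolume) -> np.ndarray:
    """Symmetric grey-level co-occurrence counts at distance 1,
    13 directions merged."""
    _check(d)
    lev, mask = d.levels, d.mask
    C = np.zeros((d.n_levels, d.n_levels), dtype=np.int64)
    for dd in DIRECTIONS_13:
        nxt_lev = _take(lev, dd, 0)
        nxt_mask = _take(mask, dd, False)
        valid = mask & nxt_mask
        np.add.at(C, (lev[valid] - 1, nxt_lev[valid] - 1), 1)
    return C + C.T


# ------------------------------------------------------------ statistics

GLRLM_NAMES = [
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "run_length_nonuniformity",
    "run_length_nonuniformity_normalized",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
    "run_gray_level_variance",
    "run_length_variance",
    "run_entropy",
]


def glrlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    R = np.asarray(R, dtype=float)
    nr = R.sum()
    if nr <= 0:
        raise ValueError("empty run-length matrix")
    i = np.arange(1, R.shape[0] + 1)[:, None]
    j = np.arange(1, R.shape[1] + 1)[None, :]
    p = R / nr
    ri = R.sum(axis=1)
    rj = R.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    pos = p[p > 0]
    return {
        "short_run_emphasis": float((R / j**2).sum() / nr),
        "long_run_emphasis": float((R * j**2).sum() / nr),
        "gray_level_nonuniformity": float((ri**2).sum() / nr),
        "gray_level_nonuniformity_normalized": float((ri**2).sum() / nr**2),
        "run_length_nonuniformity": float((rj**2).sum() / nr),
        "run_length_nonuniformity_normalized": float((rj**2).sum() / nr**2),
        "run_percentage": float(nr / (len(DIRECTIONS_13) * n_voxels)),
        "low_gray_level_run_emphasis": float((R / i**2).sum() / nr),
        "high_gray_level_run_emphasis": float((R * i**2).sum() / nr),
        "short_run_low_gray_level_emphasis": float((R / (i**2 * j**2)).sum() / nr),
        "short_run_high_gray_level_emphasis": float((R * i**2 / j**2).sum() / nr),
        "long_run_low_gray_level_emphasis": float((R * j**2 / i**2).sum() / nr),
        "long_run_high_gray_level_emphasis": float((R * i**2 * j**2).sum() / nr),
        "run_gray_level_variance": float((p * (i - mu_i) ** 2).sum()),
        "run_length_variance": float((p * (j - mu_j) ** 2).sum()),
        "run_entropy": float(-(pos * np.log2(pos)).sum()),
    }


GLSZM_NAMES = [
    "small_zone_emphasis",
    "large_zone_emphasis",
    "zone_gray_level_nonuniformity",
    "zone_gray_level_nonuniformity_normalized",
    "zone_size_nonuniformity",
    "zone_size_nonuniformity_normalized",
    "zone_percentage",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_zone_low_gray_level_emphasis",
    "small_zone_high_gray_level_emphasis",
    "large_zone_low_gray_level_emphasis",
    "large_zone_high_gray_level_emphasis",
    "zone_gray_level_variance",
    "zone_size_variance",
    "zone_entropy",
]


def glszm_features(Z: np.ndarray, n_voxels: int) -> dict[str, float]:
    Z = np.asarray(Z, dtype=float)
    nz = Z.sum()
    if nz <= 0:
        raise ValueError("empty size-zone matrix")
    i = np.arange(1, Z.shape[0] + 1)[:, None]
    j = np.arange(1, Z.shape[1] + 1)[None, :]
    p = Z / nz
    zi = Z.sum(axis=1)
    zj = Z.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    pos = p[p > 0]
    return {
        "small_zone_emphasis": float((Z / j**2).sum() / nz),
        "large_zone_emphasis": float((Z * j**2).sum() / nz),
        "zone_gray_level_nonuniformity": float((zi**2).sum() / nz),
        "zone_gray_level_nonuniformity_normalized": float((zi**2).sum() / nz**2),
        "zone_size_nonuniformity": float((zj**2).sum() / nz),
        "zone_size_nonuniformity_normalized": float((zj**2).sum() / nz**2),
        "zone_percentage": float(nz / n_voxels),
        "low_gray_level_zone_emphasis": float((Z / i**2).sum() / nz),
        "high_gray_level_zone_emphasis": float((Z * i**2).sum() / nz),
        "small_zone_low_gray_level_emphasis": float((Z / (i**2 * j**2)).sum() / nz),
        "small_zone_high_gray_level_emphasis": float((Z * i**2 / j**2).sum() / nz),
        "large_zone_low_gray_level_emphasis": float((Z * j**2 / i**2).sum() / nz),
        "large_zone_high_gray_level_emphasis": float((Z * i**2 * j**2).sum() / nz),
        "zone_gray_level_variance": float((p * (i - mu_i) ** 2).sum()),
        "zone_size_variance": float((p * (j - mu_j) ** 2).sum()),
        "zone_entropy": float(-(pos * np.log2(pos)).sum()),
    }


GLCM_NAMES = [
    "glcm_joint_energy",
    "glcm_joint_entropy",
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_inverse_difference",
    "glcm_inverse_difference_normalized",
    "glcm_inverse_difference_moment",
    "glcm_inverse_difference_moment_normalized",
    "glcm_correlation",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_autocorrelation",
]


def glcm_features(C: np.ndarray) -> dict[str, float]:
    C = np.asarray(C, dtype=float)
    total = C.sum()
    if total <= 0:
        raise ValueError("empty co-occurrence matrix")
    P = C / total
    G = P.shape[0]
    i = np.arange(1, G + 1)[:, None]
    j = np.arange(1, G + 1)[None, :]
    diff = np.abs(i - j)
    mu = float((P * i).sum())  # symmetric: row and column means equal
    sigma2 = float((P * (i - mu) ** 2).sum())
    pos = P[P > 0]
    corr = 0.0 if sigma2 == 0 else float(((i - mu) * (j - mu) * P).sum() / sigma2)
    return {
        "glcm_joint_energy": float((P**2).sum()),
        "glcm_joint_entropy": float(-(pos * np.log2(pos)).sum()),
        "glcm_contrast": float((P * (i - j) ** 2).sum()),
        "glcm_dissimilarity": float((P * diff).sum()),
        "glcm_inverse_difference": float((P / (1 + diff)).sum()),
        "glcm_inverse_difference_normalized": float((P / (1 + diff / G)).sum()),
        "glcm_inverse_difference_moment": float((P / (1 + (i - j) ** 2)).sum()),
        "glcm_inverse_difference_moment_normalized": float(
            (P / (1 + ((i - j) / G) ** 2)).sum()
        ),
        "glcm_correlation": corr,
        "glcm_cluster_shade": float((P * (i + j - 2 * mu) ** 3).sum()),
        "glcm_cluster_prominence": float((P * (i + j - 2 * mu) ** 4).sum()),
        "glcm_autocorrelation": float((P * i * j).sum()),
    }


NGTDM_NAMES = [
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
]

_OFFSETS_26 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]


def ngtdm_features(d: DiscretizedVolume) -> dict[str, float]:
    """Neighbouring grey-tone difference features (coarseness, contrast,
    busyness, complexity, strength) over the 26-neighbourhood."""
    _check(d)
    lev, mask = d.levels, d.mask
    nb_sum = np.zeros(lev.shape, dtype=float)
    nb_cnt = np.zeros(lev.shape, dtype=float)
    for dd in _OFFSETS_26:
        nb_sum += np.where(_take(mask, dd, False), _take(lev, dd, 0), 0.0)
        nb_cnt += _take(mask, dd, False).astype(float)
    use = mask & (nb_cnt > 0)
    avg = np.zeros(lev.shape)
    avg[use] = nb_sum[use] / nb_cnt[use]
    nvc = int(use.sum())
    G = d.n_levels
    n_i = np.zeros(G)
    s_i = np.zeros(G)
    lv = lev[use]
    np.add.at(n_i, lv - 1, 1.0)
    np.add.at(s_i, lv - 1, np.abs(lv - avg[use]))
    p_i = n_i / nvc
    present = p_i > 0
    gl = np.arange(1, G + 1, dtype=float)
    ngp = int(present.sum())

    ps = float((p_i * s_i).sum())
    coarseness = 1e6 if ps == 0 else float(1.0 / ps)

    if ngp <= 1:
        contrast = 0.0
    else:
        pij = p_i[present][:, None] * p_i[present][None, :]
        dij2 = (gl[present][:, None] - gl[present][None, :]) ** 2
        contrast = float((pij * dij2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nvc)

    ipi = gl[present] * p_i[present]
    denom_bus = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = 0.0 if denom_bus == 0 else float(ps / denom_bus)

    pp = p_i[present]
    ss = s_i[present]
    gg = gl[present]
    dif = np.abs(gg[:, None] - gg[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        comp = dif * (pp[:, None] * ss[:, None] + pp[None, :] * ss[None, :]) / (
            pp[:, None] + pp[None, :]
        )
    complexity = float(np.nansum(comp) / nvc)

    ssum = float(ss.sum())
    if ssum == 0:
        strength = 0.0
    else:
        strength = float(
            ((pp[:, None] + pp[None, :]) * (gg[:, None] - gg[None, :]) ** 2).sum()
            / ssum
        )
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }
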