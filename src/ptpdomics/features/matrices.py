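"""Texture-matrix feature families on a discretized grey-level grid.

Five families over the 26-neighbourhood of the 3D grid:

* GLCM  — grey-level co-occurrence, symmetric, one matrix per unique
  offset at Chebyshev distance 1 (13 offsets), features averaged over
  offsets;
* GLRLM — grey-level run lengths along the same 13 directions, features
  averaged over directions;
* GLSZM — grey-level size zones (26-connected components per level);
* GLDM  — grey-level dependence (count of equal-level neighbours; the
  dependence index includes the centre voxel, so it starts at 1);
* NGTDM — neighbourhood grey-tone difference.

Degenerate limits are fixed conventions rather than errors: a
single-level region has Correlation = Idn = Idmn = 1 and
InverseVariance = Contrast = 0.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedGrid

__all__ = [
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "OFFSETS_13",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_zones",
    "glszm_features",
    "gldm_matrix",
    "gldm_features",
    "ngtdm_table",
    "ngtdm_features",
    "matrix_features",
]

_EPS = np.finfo(np.float64).tiny

#: The 13 unique 3D offsets at Chebyshev distance 1 (lexicographically positive half).
OFFSETS_13 = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)
_OFFSETS_26 = tuple(d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0))

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def _shifted_views(levels: np.ndarray, offset: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views A (base) and B (base shifted by ``offset``)."""
    sl_a, sl_b = [], []
    for dim, delta in enumerate(offset):
        n = levels.shape[dim]
        if delta == 1:
            sl_a.append(slice(0, n - 1))
            sl_b.append(slice(1, n))
        elif delta == -1:
            sl_a.append(slice(1, n))
            sl_b.append(slice(0, n - 1))
        else:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
    return levels[tuple(sl_a)], levels[tuple(sl_b)]


# ---------------------------------------------------------------------- GLCM

def glcm_matrix(grid: DiscretizedGrid, offset: tuple) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix p(i, j) for one offset."""
    ng = grid.n_levels
    a, b = _shifted_views(grid.levels, offset)
    valid = (a > 0) & (b > 0)
    idx = (a[valid] - 1) * ng + (b[valid] - 1)
    counts = np.bincount(idx, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:  # isolated voxels only: degenerate, uniform diagonal
        counts = np.eye(ng)
        total = ng
    return counts / total


def glcm_features(p: np.ndarray) -> dict:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    # diagonal / cross-diagonal marginals
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=ng)
    k_diff = np.arange(ng)
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    k_sum = np.arange(2, 2 * ng + 1)

    hx = float(-(px * np.log2(px + _EPS)).sum())
    hxy = float(-(p * np.log2(p + _EPS)).sum())
    pxpy = px[:, None] * px[None, :]
    hxy1 = float(-(p * np.log2(pxpy + _EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())

    autocorr = float((ii * jj * p).sum())
    if sigma > 0:
        correlation = (autocorr - mu * mu) / sigma2
    else:
        correlation = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    da = float((k_diff * p_diff).sum())
    off_diag = ii != jj
    inv_var = float((p[off_diag] / (ii - jj)[off_diag].astype(float) ** 2).sum())

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff * np.log2(p_diff + _EPS)).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-(p_sum * np.log2(p_sum + _EPS)).sum()),
        "SumSquares": sigma2,
    }


# --------------------------------------------------------------------- GLRLM

def glrlm_matrix(grid: DiscretizedGrid, direction: tuple) -> np.ndarray:
    """Run-length matrix R[level-1, length-1] along one direction."""
    levels = grid.levels
    coords = np.argwhere(levels > 0)
    lv = levels[levels > 0]
    lead = next(k for k in range(3) if direction[k] != 0)
    t = coords[:, lead]  # increments by 1 per step along the direction
    d = np.asarray(direction)
    line = coords - t[:, None] * d
    order = np.lexsort((t, line[:, 2], line[:, 1], line[:, 0]))
    t_s, lv_s, line_s = t[order], lv[order], line[order]
    new_run = np.ones(len(lv_s), dtype=bool)
    if len(lv_s) > 1:
        same_line = np.all(line_s[1:] == line_s[:-1], axis=1)
        contiguous = np.diff(t_s) == 1
        same_level = np.diff(lv_s) == 0
        new_run[1:] = ~(same_line & contiguous & same_level)
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, len(lv_s)))
    run_levels = lv_s[starts]
    max_len = int(lengths.max())
    mat = np.zeros((grid.n_levels, max_len), dtype=np.float64)
    np.add.at(mat, (run_levels - 1, lengths - 1), 1.0)
    return mat


def _weighted_stats(mat: np.ndarray) -> tuple:
    ng, nl = mat.shape
    g = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, nl + 1, dtype=np.float64)
    total = mat.sum()
    return g, j, total


def glrlm_features(mat: np.ndarray, n_voxels: int) -> dict:
    g, j, nr = _weighted_stats(mat)
    gg = g[:, None]
    jj = j[None, :]
    p = mat / nr
    mu_g = float((gg * p).sum())
    mu_j = float((jj * p).sum())
    nz = p[p > 0]
    return {
        "ShortRunEmphasis": float((mat / jj**2).sum() / nr),
        "LongRunEmphasis": float((mat * jj**2).sum() / nr),
        "GrayLevelNonUniformity": float((mat.sum(1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((mat.sum(1) ** 2).sum() / nr**2),
        "RunLengthNonUniformity": float((mat.sum(0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((mat.sum(0) ** 2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float(((gg - mu_g) ** 2 * p).sum()),
        "RunVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "RunEntropy": float(-(nz * np.log2(nz)).sum()),
        "LowGrayLevelRunEmphasis": float((mat / gg**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((mat * gg**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((mat / (gg**2 * jj**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((mat * gg**2 / jj**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((mat * jj**2 / gg**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((mat * gg**2 * jj**2).sum() / nr),
    }


# --------------------------------------------------------------------- GLSZM

def glszm_zones(grid: DiscretizedGrid) -> tuple[np.ndarray, np.ndarray]:
    """26-connected zones: per-zone (level, size) arrays."""
    structure = np.ones((3, 3, 3), dtype=bool)
    zone_levels, zone_sizes = [], []
    for level in range(1, grid.n_levels + 1):
        labelled, n_zones = ndimage.label(grid.levels == level, structure=structure)
        if n_zones:
            sizes = np.bincount(labelled.ravel())[1:]
            zone_levels.extend([level] * n_zones)
            zone_sizes.extend(sizes.tolist())
    return np.asarray(zone_levels, dtype=np.float64), np.asarray(zone_sizes, dtype=np.float64)


def glszm_features(zone_levels: np.ndarray, zone_sizes: np.ndarray, n_voxels: int) -> dict:
    nz = float(len(zone_levels))
    g, s = zone_levels, zone_sizes
    # aggregate counts per level and per size for the non-uniformity terms
    per_level = np.bincount(g.astype(int))[1:].astype(np.float64)
    uniq_sizes, size_counts = np.unique(s, return_counts=True)
    mu_g = g.sum() / nz
    mu_s = s.sum() / nz
    # zone-size distribution entropy over (level, size) cells
    cells = {}
    for gi, si in zip(g, s):
        cells[(gi, si)] = cells.get((gi, si), 0) + 1
    pcell = np.asarray(list(cells.values()), dtype=np.float64) / nz
    return {
        "SmallAreaEmphasis": float((1.0 / s**2).sum() / nz),
        "LargeAreaEmphasis": float((s**2).sum() / nz),
        "GrayLevelNonUniformity": float((per_level**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((per_level**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((size_counts.astype(np.float64) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((size_counts.astype(np.float64) ** 2).sum() / nz**2),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float(((g - mu_g) ** 2).sum() / nz),
        "ZoneVariance": float(((s - mu_s) ** 2).sum() / nz),
        "ZoneEntropy": float(-(pcell * np.log2(pcell)).sum()),
        "LowGrayLevelZoneEmphasis": float((1.0 / g**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((g**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((1.0 / (g**2 * s**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((g**2 / s**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((s**2 / g**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((g**2 * s**2).sum() / nz),
    }


# ---------------------------------------------------------------------- GLDM

def gldm_matrix(grid: DiscretizedGrid) -> np.ndarray:
    """Dependence matrix D[level-1, j-1]: j = 1 + count of 26-neighbours
    inside the VOI sharing the voxel's grey level."""
    levels = grid.levels
    padded = np.pad(levels, 1)
    centre = padded[1:-1, 1:-1, 1:-1]
    dep = np.zeros(levels.shape, dtype=np.int64)
    for dz, dy, dx in _OFFSETS_26:
        nb = padded[1 + dz : padded.shape[0] - 1 + dz,
                    1 + dy : padded.shape[1] - 1 + dy,
                    1 + dx : padded.shape[2] - 1 + dx]
        dep += (nb == centre) & (centre > 0) & (nb > 0)
    inside = levels > 0
    j = dep[inside] + 1  # centre voxel always depends on itself
    g = levels[inside]
    max_j = int(j.max())
    mat = np.zeros((grid.n_levels, max_j), dtype=np.float64)
    np.add.at(mat, (g - 1, j - 1), 1.0)
    return mat


def gldm_features(mat: np.ndarray) -> dict:
    g, j, nz = _weighted_stats(mat)
    gg, jj = g[:, None], j[None, :]
    p = mat / nz
    mu_g = float((gg * p).sum())
    mu_j = float((jj * p).sum())
    pn = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((mat / jj**2).sum() / nz),
        "LargeDependenceEmphasis": float((mat * jj**2).sum() / nz),
        "GrayLevelNonUniformity": float((mat.sum(1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((mat.sum(0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((mat.sum(0) ** 2).sum() / nz**2),
        "GrayLevelVariance": float(((gg - mu_g) ** 2 * p).sum()),
        "DependenceVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "DependenceEntropy": float(-(pn * np.log2(pn)).sum()),
        "LowGrayLevelEmphasis": float((mat / gg**2).sum() / nz),
        "HighGrayLevelEmphasis": float((mat * gg**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((mat / (gg**2 * jj**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((mat * gg**2 / jj**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((mat * jj**2 / gg**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((mat * gg**2 * jj**2).sum() / nz),
    }


# --------------------------------------------------------------------- NGTDM

def ngtdm_table(grid: DiscretizedGrid) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_g, s_g) and the count of voxels with a valid
    neighbourhood.  s_g sums |level - mean of in-VOI 26-neighbours|."""
    levels = grid.levels
    padded = np.pad(levels, 1)
    centre = padded[1:-1, 1:-1, 1:-1]
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for dz, dy, dx in _OFFSETS_26:
        nb = padded[1 + dz : padded.shape[0] - 1 + dz,
                    1 + dy : padded.shape[1] - 1 + dy,
                    1 + dx : padded.shape[2] - 1 + dx]
        ok = (nb > 0)
        nb_sum += np.where(ok, nb, 0)
        nb_cnt += ok
    valid = (levels > 0) & (nb_cnt > 0)
    ng = grid.n_levels
    n_i = np.zeros(ng, dtype=np.float64)
    s_i = np.zeros(ng, dtype=np.float64)
    lv = levels[valid]
    diff = np.abs(lv - nb_sum[valid] / nb_cnt[valid])
    np.add.at(n_i, lv - 1, 1.0)
    np.add.at(s_i, lv - 1, diff)
    return n_i, s_i, int(valid.sum())


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray, n_valid: int) -> dict:
    if n_valid == 0:
        return {name: 0.0 for name in NGTDM_NAMES}
    ng = len(n_i)
    i = np.arange(1, ng + 1, dtype=np.float64)
    p = n_i / n_valid
    act = p > 0
    ngp = int(act.sum())
    ia, pa, sa = i[act], p[act], s_i[act]

    coarse_den = float((pa * sa).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        dif2 = (ia[:, None] - ia[None, :]) ** 2
        pp = pa[:, None] * pa[None, :]
        contrast = float((pp * dif2).sum()) / (ngp * (ngp - 1)) * float(sa.sum()) / n_valid
        busy_den = float(np.abs(ia[:, None] * pa[:, None] - ia[None, :] * pa[None, :]).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        absdif = np.abs(ia[:, None] - ia[None, :])
        num = (pa[:, None] * sa[:, None] + pa[None, :] * sa[None, :])
        complexity = float((absdif * num / (pa[:, None] + pa[None, :])).sum()) / n_valid
        s_total = float(sa.sum())
        strength = float(((pa[:, None] + pa[None, :]) * dif2).sum()) / s_total if s_total > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ------------------------------------------------------------------ together

def matrix_features(grid: DiscretizedGrid) -> dict:
    """All five matrix families; keys are ``family__name``."""
    n_voxels = int((grid.levels > 0).sum())
    out = {}

    acc = {name: 0.0 for name in GLCM_NAMES}
    for off in OFFSETS_13:
        feats = glcm_features(glcm_matrix(grid, off))
        for name in GLCM_NAMES:
            acc[name] += feats[name]
    out.update({f"glcm__{k}": v / len(OFFSETS_13) for k, v in acc.items()})

    acc = {name: 0.0 for name in GLRLM_NAMES}
    for off in OFFSETS_13:
        feats = glrlm_features(glrlm_matrix(grid, off), n_voxels)
        for name in GLRLM_NAMES:
            acc[name] += feats[name]
    out.update({f"glrlm__{k}": v / len(OFFSETS_13) for k, v in acc.items()})

    zl, zs = glszm_zones(grid)
    out.update({f"glszm__{k}": v for k, v in glszm_features(zl, zs, n_voxels).items()})
    out.update({f"gldm__{k}": v for k, v in gldm_features(gldm_matrix(grid)).items()})
    out.update({f"ngtdm__{k}": v for k, v in ngtdm_features(*ngtdm_table(grid)).items()})
    return out
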