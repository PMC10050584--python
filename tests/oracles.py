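"""Independent brute-force oracles for the texture-matrix features.

Everything here is written as plain nested loops over voxels and matrix
cells, deliberately sharing no code with the package implementation.
Grids are small integer-level arrays (0 = outside the VOI).
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

OFFSETS_13 = [d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
OFFSETS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _in_bounds(p, shape):
    return all(0 <= p[i] < shape[i] for i in range(3))


# ----------------------------------------------------------------- GLCM

def naive_glcm(levels: np.ndarray, offset, ng: int) -> np.ndarray:
    counts = np.zeros((ng, ng))
    for z in range(levels.shape[0]):
        for y in range(levels.shape[1]):
            for x in range(levels.shape[2]):
                a = levels[z, y, x]
                if a == 0:
                    continue
                q = (z + offset[0], y + offset[1], x + offset[2])
                if _in_bounds(q, levels.shape):
                    b = levels[q]
                    if b > 0:
                        counts[a - 1, b - 1] += 1
                        counts[b - 1, a - 1] += 1
    total = counts.sum()
    if total == 0:
        counts = np.eye(ng)
        total = ng
    return counts / total


def naive_glcm_features(p: np.ndarray) -> dict:
    ng = p.shape[0]
    out = {}
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))

    def s(term):
        return sum(term(i, j) for i in range(ng) for j in range(ng))

    out["Autocorrelation"] = s(lambda i, j: (i + 1) * (j + 1) * p[i][j])
    out["ClusterProminence"] = s(lambda i, j: (i + j + 2 - 2 * mu) ** 4 * p[i][j])
    out["ClusterShade"] = s(lambda i, j: (i + j + 2 - 2 * mu) ** 3 * p[i][j])
    out["ClusterTendency"] = s(lambda i, j: (i + j + 2 - 2 * mu) ** 2 * p[i][j])
    out["Contrast"] = s(lambda i, j: (i - j) ** 2 * p[i][j])
    out["Correlation"] = (
        (out["Autocorrelation"] - mu * mu) / var if var > 0 else 1.0
    )
    pd_ = [0.0] * ng
    ps = [0.0] * (2 * ng - 1)  # k = i+j, 2..2ng
    for i in range(ng):
        for j in range(ng):
            pd_[abs(i - j)] += p[i][j]
            ps[i + j] += p[i][j]
    da = sum(k * pd_[k] for k in range(ng))
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = -sum(v * math.log2(v) for v in pd_ if v > 0)
    out["DifferenceVariance"] = sum((k - da) ** 2 * pd_[k] for k in range(ng))
    out["Id"] = s(lambda i, j: p[i][j] / (1 + abs(i - j)))
    out["Idm"] = s(lambda i, j: p[i][j] / (1 + (i - j) ** 2))
    out["Idmn"] = s(lambda i, j: p[i][j] / (1 + ((i - j) / ng) ** 2))
    out["Idn"] = s(lambda i, j: p[i][j] / (1 + abs(i - j) / ng))
    hxy = -s(lambda i, j: p[i][j] * math.log2(p[i][j]) if p[i][j] > 0 else 0.0)
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hxy1 = -s(
        lambda i, j: p[i][j] * math.log2(px[i] * px[j]) if p[i][j] > 0 and px[i] * px[j] > 0 else 0.0
    )
    hxy2 = -s(
        lambda i, j: px[i] * px[j] * math.log2(px[i] * px[j]) if px[i] * px[j] > 0 else 0.0
    )
    out["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    out["Imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    out["InverseVariance"] = s(
        lambda i, j: p[i][j] / (i - j) ** 2 if i != j else 0.0
    )
    out["JointAverage"] = mu
    out["JointEnergy"] = s(lambda i, j: p[i][j] ** 2)
    out["JointEntropy"] = hxy
    out["MaximumProbability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    out["SumEntropy"] = -sum(v * math.log2(v) for v in ps if v > 0)
    out["SumSquares"] = var
    return out


# ---------------------------------------------------------------- GLRLM

def naive_runs(levels: np.ndarray, direction) -> list:
    """All (level, run length) runs along one direction, walking lines."""
    runs = []
    shape = levels.shape
    d = direction
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                prev = (z - d[0], y - d[1], x - d[2])
                lv = levels[z, y, x]
                if lv == 0:
                    continue
                # start of a run only if predecessor is absent or different
                if _in_bounds(prev, shape) and levels[prev] == lv:
                    continue
                length = 1
                cur = (z + d[0], y + d[1], x + d[2])
                while _in_bounds(cur, shape) and levels[cur] == lv:
                    length += 1
                    cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                runs.append((int(lv), length))
    return runs


def naive_glrlm_features(runs: list, ng: int, n_voxels: int) -> dict:
    nr = len(runs)
    out = {
        "ShortRunEmphasis": sum(1 / j**2 for _, j in runs) / nr,
        "LongRunEmphasis": sum(j**2 for _, j in runs) / nr,
        "RunPercentage": nr / n_voxels,
        "LowGrayLevelRunEmphasis": sum(1 / g**2 for g, _ in runs) / nr,
        "HighGrayLevelRunEmphasis": sum(g**2 for g, _ in runs) / nr,
        "ShortRunLowGrayLevelEmphasis": sum(1 / (g**2 * j**2) for g, j in runs) / nr,
        "ShortRunHighGrayLevelEmphasis": sum(g**2 / j**2 for g, j in runs) / nr,
        "LongRunLowGrayLevelEmphasis": sum(j**2 / g**2 for g, j in runs) / nr,
        "LongRunHighGrayLevelEmphasis": sum(g**2 * j**2 for g, j in runs) / nr,
    }
    per_level = {}
    per_length = {}
    cells = {}
    for g, j in runs:
        per_level[g] = per_level.get(g, 0) + 1
        per_length[j] = per_length.get(j, 0) + 1
        cells[(g, j)] = cells.get((g, j), 0) + 1
    out["GrayLevelNonUniformity"] = sum(c**2 for c in per_level.values()) / nr
    out["GrayLevelNonUniformityNormalized"] = sum(c**2 for c in per_level.values()) / nr**2
    out["RunLengthNonUniformity"] = sum(c**2 for c in per_length.values()) / nr
    out["RunLengthNonUniformityNormalized"] = sum(c**2 for c in per_length.values()) / nr**2
    mu_g = sum(g for g, _ in runs) / nr
    mu_j = sum(j for _, j in runs) / nr
    out["GrayLevelVariance"] = sum((g - mu_g) ** 2 for g, _ in runs) / nr
    out["RunVariance"] = sum((j - mu_j) ** 2 for _, j in runs) / nr
    out["RunEntropy"] = -sum(
        (c / nr) * math.log2(c / nr) for c in cells.values()
    )
    return out


# ---------------------------------------------------------------- GLSZM

def naive_zones(levels: np.ndarray) -> list:
    """(level, size) of every 26-connected zone, BFS flood fill."""
    visited = np.zeros(levels.shape, dtype=bool)
    zones = []
    for z in range(levels.shape[0]):
        for y in range(levels.shape[1]):
            for x in range(levels.shape[2]):
                if levels[z, y, x] == 0 or visited[z, y, x]:
                    continue
                lv = levels[z, y, x]
                stack = [(z, y, x)]
                visited[z, y, x] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in OFFSETS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if (
                            _in_bounds(q, levels.shape)
                            and not visited[q]
                            and levels[q] == lv
                        ):
                            visited[q] = True
                            stack.append(q)
                zones.append((int(lv), size))
    return zones


def naive_glszm_features(zones: list, n_voxels: int) -> dict:
    nz = len(zones)
    per_level = {}
    per_size = {}
    cells = {}
    for g, s in zones:
        per_level[g] = per_level.get(g, 0) + 1
        per_size[s] = per_size.get(s, 0) + 1
        cells[(g, s)] = cells.get((g, s), 0) + 1
    mu_g = sum(g for g, _ in zones) / nz
    mu_s = sum(s for _, s in zones) / nz
    return {
        "SmallAreaEmphasis": sum(1 / s**2 for _, s in zones) / nz,
        "LargeAreaEmphasis": sum(s**2 for _, s in zones) / nz,
        "GrayLevelNonUniformity": sum(c**2 for c in per_level.values()) / nz,
        "GrayLevelNonUniformityNormalized": sum(c**2 for c in per_level.values()) / nz**2,
        "SizeZoneNonUniformity": sum(c**2 for c in per_size.values()) / nz,
        "SizeZoneNonUniformityNormalized": sum(c**2 for c in per_size.values()) / nz**2,
        "ZonePercentage": nz / n_voxels,
        "GrayLevelVariance": sum((g - mu_g) ** 2 for g, _ in zones) / nz,
        "ZoneVariance": sum((s - mu_s) ** 2 for _, s in zones) / nz,
        "ZoneEntropy": -sum((c / nz) * math.log2(c / nz) for c in cells.values()),
        "LowGrayLevelZoneEmphasis": sum(1 / g**2 for g, _ in zones) / nz,
        "HighGrayLevelZoneEmphasis": sum(g**2 for g, _ in zones) / nz,
        "SmallAreaLowGrayLevelEmphasis": sum(1 / (g**2 * s**2) for g, s in zones) / nz,
        "SmallAreaHighGrayLevelEmphasis": sum(g**2 / s**2 for g, s in zones) / nz,
        "LargeAreaLowGrayLevelEmphasis": sum(s**2 / g**2 for g, s in zones) / nz,
        "LargeAreaHighGrayLevelEmphasis": sum(g**2 * s**2 for g, s in zones) / nz,
    }


# ----------------------------------------------------------------- GLDM

def naive_dependences(levels: np.ndarray) -> list:
    """(level, dependence) per VOI voxel; dependence counts the centre
    plus equal-level in-VOI 26-neighbours."""
    deps = []
    for z in range(levels.shape[0]):
        for y in range(levels.shape[1]):
            for x in range(levels.shape[2]):
                lv = levels[z, y, x]
                if lv == 0:
                    continue
                count = 1
                for d in OFFSETS_26:
                    q = (z + d[0], y + d[1], x + d[2])
                    if _in_bounds(q, levels.shape) and levels[q] == lv:
                        count += 1
                deps.append((int(lv), count))
    return deps


def naive_gldm_features(deps: list) -> dict:
    nz = len(deps)
    per_level = {}
    per_dep = {}
    cells = {}
    for g, j in deps:
        per_level[g] = per_level.get(g, 0) + 1
        per_dep[j] = per_dep.get(j, 0) + 1
        cells[(g, j)] = cells.get((g, j), 0) + 1
    mu_g = sum(g for g, _ in deps) / nz
    mu_j = sum(j for _, j in deps) / nz
    return {
        "SmallDependenceEmphasis": sum(1 / j**2 for _, j in deps) / nz,
        "LargeDependenceEmphasis": sum(j**2 for _, j in deps) / nz,
        "GrayLevelNonUniformity": sum(c**2 for c in per_level.values()) / nz,
        "DependenceNonUniformity": sum(c**2 for c in per_dep.values()) / nz,
        "DependenceNonUniformityNormalized": sum(c**2 for c in per_dep.values()) / nz**2,
        "GrayLevelVariance": sum((g - mu_g) ** 2 for g, _ in deps) / nz,
        "DependenceVariance": sum((j - mu_j) ** 2 for _, j in deps) / nz,
        "DependenceEntropy": -sum((c / nz) * math.log2(c / nz) for c in cells.values()),
        "LowGrayLevelEmphasis": sum(1 / g**2 for g, _ in deps) / nz,
        "HighGrayLevelEmphasis": sum(g**2 for g, _ in deps) / nz,
        "SmallDependenceLowGrayLevelEmphasis": sum(1 / (g**2 * j**2) for g, j in deps) / nz,
        "SmallDependenceHighGrayLevelEmphasis": sum(g**2 / j**2 for g, j in deps) / nz,
        "LargeDependenceLowGrayLevelEmphasis": sum(j**2 / g**2 for g, j in deps) / nz,
        "LargeDependenceHighGrayLevelEmphasis": sum(g**2 * j**2 for g, j in deps) / nz,
    }


# ---------------------------------------------------------------- NGTDM

def naive_ngtdm_features(levels: np.ndarray, ng: int) -> dict:
    n_i = [0] * (ng + 1)
    s_i = [0.0] * (ng + 1)
    n_valid = 0
    for z in range(levels.shape[0]):
        for y in range(levels.shape[1]):
            for x in range(levels.shape[2]):
                lv = levels[z, y, x]
                if lv == 0:
                    continue
                nb = []
                for d in OFFSETS_26:
                    q = (z + d[0], y + d[1], x + d[2])
                    if _in_bounds(q, levels.shape) and levels[q] > 0:
                        nb.append(levels[q])
                if not nb:
                    continue
                n_valid += 1
                n_i[lv] += 1
                s_i[lv] += abs(lv - sum(nb) / len(nb))
    if n_valid == 0:
        return {k: 0.0 for k in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")}
    p = [n_i[g] / n_valid for g in range(ng + 1)]
    active = [g for g in range(1, ng + 1) if p[g] > 0]
    ngp = len(active)
    coarse_den = sum(p[g] * s_i[g] for g in active)
    coarseness = 1 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in active for j in active)
            / (ngp * (ngp - 1))
            * sum(s_i[g] for g in active)
            / n_valid
        )
        busy_den = sum(abs(i * p[i] - j * p[j]) for i in active for j in active)
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
                for i in active
                for j in active
            )
            / n_valid
        )
        s_total = sum(s_i[g] for g in active)
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in active for j in active) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def naive_all_matrix_features(levels: np.ndarray, ng: int) -> dict:
    """Every matrix-family feature, keys ``family__name``."""
    n_vox = int((levels > 0).sum())
    out = {}
    acc: dict = {}
    for off in OFFSETS_13:
        feats = naive_glcm_features(naive_glcm(levels, off, ng))
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v
    out.update({f"glcm__{k}": v / len(OFFSETS_13) for k, v in acc.items()})
    acc = {}
    for off in OFFSETS_13:
        feats = naive_glrlm_features(naive_runs(levels, off), ng, n_vox)
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v
    out.update({f"glrlm__{k}": v / len(OFFSETS_13) for k, v in acc.items()})
    out.update({f"glszm__{k}": v for k, v in naive_glszm_features(naive_zones(levels), n_vox).items()})
    out.update({f"gldm__{k}": v for k, v in naive_gldm_features(naive_dependences(levels)).items()})
    out.update({f"ngtdm__{k}": v for k, v in naive_ngtdm_features(levels, ng).items()})
    return out
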