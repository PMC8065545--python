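"""Independent brute-force oracles for the test suite.

Everything here is written as naive pure-Python enumeration — voxel-pair
loops, run walking, flood fill, per-voxel neighbourhood scans, exact
hypergeometric sums, exhaustive within-subject rank permutations — kept
deliberately separate from the package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

OFFSETS_13 = [
    (dx, dy, dz)
    for dz in (0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]
NEIGHBORS_26 = [off for off in itertools.product((-1, 0, 1), repeat=3)
                if off != (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= c < n for c, n in zip(v, shape))


# ---------------------------------------------------------------------------
# texture matrices by enumeration
# ---------------------------------------------------------------------------

def brute_glcm(levels: np.ndarray, mask: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Symmetrized co-occurrence counts per direction via voxel-pair loops."""
    shape = mask.shape
    mats = []
    for off in OFFSETS_13:
        m = np.zeros((n_bins + 1, n_bins + 1))
        for v in np.argwhere(mask):
            w = tuple(v + off)
            if _inside(shape, w) and mask[w]:
                a, b = levels[tuple(v)], levels[w]
                m[a, b] += 1
                m[b, a] += 1
        mats.append(m)
    return mats


def brute_glrlm(levels: np.ndarray, mask: np.ndarray, n_bins: int,
                max_len: int) -> list[np.ndarray]:
    """Run-length counts per direction by walking maximal runs."""
    shape = mask.shape
    mats = []
    for off in OFFSETS_13:
        m = np.zeros((n_bins + 1, max_len + 1))
        for v in np.argwhere(mask):
            g = levels[tuple(v)]
            prev = tuple(v - off)
            if _inside(shape, prev) and mask[prev] and levels[prev] == g:
                continue  # not the start of a run
            length = 1
            cur = tuple(v + off)
            while _inside(shape, cur) and mask[cur] and levels[cur] == g:
                length += 1
                cur = tuple(np.array(cur) + off)
            m[g, length] += 1
        mats.append(m)
    return mats


def brute_glszm(levels: np.ndarray, mask: np.ndarray, n_bins: int,
                max_size: int) -> np.ndarray:
    """Size-zone counts via BFS flood fill over 26-connected equal-level zones."""
    visited = np.zeros_like(mask, dtype=bool)
    m = np.zeros((n_bins + 1, max_size + 1))
    shape = mask.shape
    for v0 in map(tuple, np.argwhere(mask)):
        if visited[v0]:
            continue
        g = levels[v0]
        stack = [v0]
        visited[v0] = True
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for off in NEIGHBORS_26:
                w = tuple(np.array(v) + off)
                if (_inside(shape, w) and mask[w] and not visited[w]
                        and levels[w] == g):
                    visited[w] = True
                    stack.append(w)
        m[g, size] += 1
    return m


def brute_ngtdm(levels: np.ndarray, mask: np.ndarray):
    """(levels, n_i, s_i, Nvp) via per-voxel 26-neighbourhood scans."""
    shape = mask.shape
    per_level_n: dict[int, int] = {}
    per_level_s: dict[int, float] = {}
    nvp = 0
    for v in map(tuple, np.argwhere(mask)):
        nbrs = []
        for off in NEIGHBORS_26:
            w = tuple(np.array(v) + off)
            if _inside(shape, w) and mask[w]:
                nbrs.append(levels[w])
        if not nbrs:
            continue
        nvp += 1
        g = int(levels[v])
        per_level_n[g] = per_level_n.get(g, 0) + 1
        per_level_s[g] = per_level_s.get(g, 0.0) + abs(g - sum(nbrs) / len(nbrs))
    lv = sorted(per_level_n)
    return (np.array(lv, dtype=float),
            np.array([per_level_n[g] for g in lv], dtype=float),
            np.array([per_level_s[g] for g in lv], dtype=float), nvp)


# ---------------------------------------------------------------------------
# texture features by naive summation
# ---------------------------------------------------------------------------

def glcm_features_naive(counts: np.ndarray) -> dict[str, float] | None:
    """The 24 co-occurrence features as explicit sums over matrix entries."""
    total = counts.sum()
    if total == 0:
        return None
    entries = [(i, j, counts[i, j] / total)
               for i in range(counts.shape[0]) for j in range(counts.shape[1])
               if counts[i, j] > 0]
    occ = sorted({i for i, _, _ in entries} | {j for _, j, _ in entries})
    ng = len(occ)
    px = {i: sum(p for a, _, p in entries if a == i) for i in occ}
    mu = sum(i * px[i] for i in occ)
    sigma2 = sum((i - mu) ** 2 * px[i] for i in occ)
    p_diff: dict[int, float] = {}
    p_sum: dict[int, float] = {}
    for i, j, p in entries:
        p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p
        p_sum[i + j] = p_sum.get(i + j, 0.0) + p
    da = sum(k * v for k, v in p_diff.items())
    hxy = -sum(p * math.log2(p) for _, _, p in entries)
    hx = -sum(v * math.log2(v) for v in px.values() if v > 0)
    hxy1 = -sum(p * math.log2(px[i] * px[j]) for i, j, p in entries
                if px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                for i in occ for j in occ if px[i] * px[j] > 0)
    autoc = sum(i * j * p for i, j, p in entries)
    corr = (autoc - mu * mu) / sigma2 if sigma2 > 0 else 1.0
    if ng > 1:
        q = np.zeros((ng, ng))
        idx = {g: a for a, g in enumerate(occ)}
        pm = np.zeros((ng, ng))
        for i, j, p in entries:
            pm[idx[i], idx[j]] = p
        pxv = pm.sum(axis=1)
        for a in range(ng):
            for b in range(ng):
                q[a, b] = sum(pm[a, k] * pm[b, k] / (pxv[a] * pxv[k])
                              for k in range(ng) if pxv[a] > 0 and pxv[k] > 0)
        eig = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, eig[-2]))
    else:
        mcc = 1.0
    return {
        "Autocorrelation": autoc,
        "ClusterProminence": sum((i + j - 2 * mu) ** 4 * p for i, j, p in entries),
        "ClusterShade": sum((i + j - 2 * mu) ** 3 * p for i, j, p in entries),
        "ClusterTendency": sum((i + j - 2 * mu) ** 2 * p for i, j, p in entries),
        "Contrast": sum((i - j) ** 2 * p for i, j, p in entries),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * math.log2(v) for v in p_diff.values() if v > 0),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "Id": sum(p / (1 + abs(i - j)) for i, j, p in entries),
        "Idm": sum(p / (1 + (i - j) ** 2) for i, j, p in entries),
        "Idmn": sum(p / (1 + (i - j) ** 2 / ng ** 2) for i, j, p in entries),
        "Idn": sum(p / (1 + abs(i - j) / ng) for i, j, p in entries),
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
        "InverseVariance": sum(p / (i - j) ** 2 for i, j, p in entries if i != j),
        "JointAverage": mu,
        "JointEnergy": sum(p ** 2 for _, _, p in entries),
        "JointEntropy": hxy,
        "MaximumProbability": max(p for _, _, p in entries),
        "MCC": mcc,
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": -sum(v * math.log2(v) for v in p_sum.values() if v > 0),
        "SumSquares": sigma2,
    }


def run_zone_features_naive(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 shared run-length/size-zone feature formulas as explicit sums,
    keyed by the generic names (Small/Large emphasis etc.)."""
    total = mat.sum()
    entries = [(i, j, mat[i, j]) for i in range(mat.shape[0])
               for j in range(mat.shape[1]) if mat[i, j] > 0]
    ri: dict[int, float] = {}
    rj: dict[int, float] = {}
    for i, j, c in entries:
        ri[i] = ri.get(i, 0.0) + c
        rj[j] = rj.get(j, 0.0) + c
    mu_i = sum(i * c for i, c in ri.items()) / total
    mu_j = sum(j * c for j, c in rj.items()) / total
    return {
        "SmallEmphasis": sum(c / j ** 2 for _, j, c in entries) / total,
        "LargeEmphasis": sum(c * j ** 2 for _, j, c in entries) / total,
        "GrayLevelNonUniformity": sum(c ** 2 for c in ri.values()) / total,
        "GrayLevelNonUniformityNormalized": sum(c ** 2 for c in ri.values()) / total ** 2,
        "SizeNonUniformity": sum(c ** 2 for c in rj.values()) / total,
        "SizeNonUniformityNormalized": sum(c ** 2 for c in rj.values()) / total ** 2,
        "Percentage": total / n_voxels,
        "GrayLevelVariance": sum((i - mu_i) ** 2 * c for i, c in ri.items()) / total,
        "SizeVariance": sum((j - mu_j) ** 2 * c for j, c in rj.items()) / total,
        "Entropy": -sum(c / total * math.log2(c / total) for _, _, c in entries),
        "LowGrayLevelEmphasis": sum(c / i ** 2 for i, _, c in entries) / total,
        "HighGrayLevelEmphasis": sum(c * i ** 2 for i, _, c in entries) / total,
        "SmallLowGrayLevelEmphasis": sum(c / (i ** 2 * j ** 2) for i, j, c in entries) / total,
        "SmallHighGrayLevelEmphasis": sum(c * i ** 2 / j ** 2 for i, j, c in entries) / total,
        "LargeLowGrayLevelEmphasis": sum(c * j ** 2 / i ** 2 for i, j, c in entries) / total,
        "LargeHighGrayLevelEmphasis": sum(c * i ** 2 * j ** 2 for i, j, c in entries) / total,
    }


def ngtdm_features_naive(levels, n_i, s_i, nvp) -> dict[str, float]:
    """The 5 neighbourhood gray-tone difference features as explicit sums."""
    if nvp == 0:
        return {"Coarseness": 1e6, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    p = n_i / nvp
    ngp = len(levels)
    dc = sum(p[a] * s_i[a] for a in range(ngp))
    coarseness = 1.0 / dc if dc > 0 else 1e6
    if ngp > 1:
        c1 = sum(p[a] * p[b] * (levels[a] - levels[b]) ** 2
                 for a in range(ngp) for b in range(ngp))
        contrast = c1 / (ngp * (ngp - 1)) * sum(s_i) / nvp
    else:
        contrast = 0.0
    db = sum(abs(levels[a] * p[a] - levels[b] * p[b])
             for a in range(ngp) for b in range(ngp))
    busyness = dc / db if db > 0 else 0.0
    complexity = sum(
        abs(levels[a] - levels[b]) * (p[a] * s_i[a] + p[b] * s_i[b]) / (p[a] + p[b])
        for a in range(ngp) for b in range(ngp) if p[a] + p[b] > 0) / nvp
    st = sum(s_i)
    strength = (sum((p[a] + p[b]) * (levels[a] - levels[b]) ** 2
                    for a in range(ngp) for b in range(ngp)) / st if st > 0 else 0.0)
    return {"Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness,
            "Complexity": complexity, "Strength": strength}


# ---------------------------------------------------------------------------
# statistical oracles
# ---------------------------------------------------------------------------

def fisher_exact_brute(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration (fixed margins)."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) < 0 or n == 0:
        return 1.0

    def prob(x):  # P(X = x) for the hypergeometric with these margins
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-7))


def friedman_permutation_p(readings: np.ndarray, statistic_fn) -> float:
    """Exact permutation p for the Friedman statistic: enumerate all k!^n
    within-subject orderings (uniform under the null)."""
    readings = np.asarray(readings, dtype=float)
    n, k = readings.shape
    q_obs, _ = statistic_fn(readings)
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = 0
    for combo in itertools.product(perms, repeat=n):
        arr = np.array([readings[i, list(combo[i])] for i in range(n)])
        q, _ = statistic_fn(arr)
        total += 1
        if q >= q_obs - 1e-12:
            count += 1
    return count / total
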