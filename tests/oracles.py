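"""Independent brute-force oracles for texture/filter features.

Every function here recomputes a feature by direct enumeration (voxel-pair
listing, BFS zone growing, run walking, triple-loop convolution, explicit
tensor-product filter bank) without sharing code with the implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def glcm_matrix_oracle(disc: np.ndarray, mask: np.ndarray, direction, n_levels: int):
    """Symmetrized normalized co-occurrence matrix by explicit pair listing."""
    mat = np.zeros((n_levels, n_levels))
    shape = disc.shape
    for z, y, x in zip(*np.nonzero(mask)):
        for sign in (+1, -1):
            nz, ny, nx = (
                z + sign * direction[0],
                y + sign * direction[1],
                x + sign * direction[2],
            )
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                if mask[nz, ny, nx]:
                    mat[disc[z, y, x] - 1, disc[nz, ny, nx] - 1] += 1
    if mat.sum() == 0:
        return None
    return mat / mat.sum()


def glcm_features_oracle(p: np.ndarray) -> dict:
    n = p.shape[0]
    joint_max = p.max()
    autocorr = sum(
        (i + 1) * (j + 1) * p[i, j] for i in range(n) for j in range(n)
    )
    pk = np.zeros(n)
    for i in range(n):
        for j in range(n):
            pk[abs(i - j)] += p[i, j]
    de = -sum(v * np.log2(v) for v in pk if v > 0)
    return {
        "joint_max": float(joint_max),
        "autocorrelation": float(autocorr),
        "difference_entropy": float(de),
    }


def glszm_counts_oracle(disc: np.ndarray, mask: np.ndarray) -> dict:
    """Zone counts via breadth-first search over the 26-neighbourhood."""
    visited = np.zeros(disc.shape, dtype=bool)
    counts: dict[tuple[int, int], int] = {}
    nbrs = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    shape = disc.shape
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        lev = disc[start]
        queue = [start]
        visited[start] = True
        size = 0
        while queue:
            v = queue.pop()
            size += 1
            for d in nbrs:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < shape[i] for i in range(3)):
                    if mask[w] and not visited[w] and disc[w] == lev:
                        visited[w] = True
                        queue.append(w)
        key = (int(lev), size)
        counts[key] = counts.get(key, 0) + 1
    return counts


def glrlm_runs_oracle(disc: np.ndarray, mask: np.ndarray, direction) -> dict:
    """Run counts by walking every full grid line in the given direction."""
    shape = disc.shape
    d = np.array(direction)
    starts = []
    for v in itertools.product(*(range(s) for s in shape)):
        prev = np.array(v) - d
        if not all(0 <= prev[i] < shape[i] for i in range(3)):
            starts.append(np.array(v))
    runs: dict[tuple[int, int], int] = {}
    for s in starts:
        v = s.copy()
        current_level, length = None, 0
        while all(0 <= v[i] < shape[i] for i in range(3)):
            inside = mask[tuple(v)]
            lev = disc[tuple(v)] if inside else None
            if inside and lev == current_level:
                length += 1
            else:
                if current_level is not None:
                    key = (int(current_level), length)
                    runs[key] = runs.get(key, 0) + 1
                current_level, length = (lev, 1) if inside else (None, 0)
            v += d
        if current_level is not None:
            key = (int(current_level), length)
            runs[key] = runs.get(key, 0) + 1
    return runs


def lglre_oracle(runs: dict) -> float:
    total = sum(runs.values())
    return sum(c / (i**2) for (i, _), c in runs.items()) / total


def conv3d_oracle(image: np.ndarray, kernels) -> np.ndarray:
    """Direct (non-separable) 3D correlation with edge replication."""
    k3 = np.einsum("i,j,k->ijk", *kernels)
    pad = 2
    padded = np.pad(image, pad, mode="edge")
    out = np.zeros_like(image, dtype=float)
    for z in range(image.shape[0]):
        for y in range(image.shape[1]):
            for x in range(image.shape[2]):
                block = padded[z : z + 5, y : y + 5, x : x + 5]
                out[z, y, x] = (block * k3).sum()
    return out


def haar_level1_oracle(image: np.ndarray) -> dict:
    """Single-level 3D orthonormal Haar bank on an even-sized volume."""
    lo = np.array([1.0, 1.0]) / np.sqrt(2.0)
    hi = np.array([1.0, -1.0]) / np.sqrt(2.0)  # pywt 'haar' detail = (x0-x1)/sqrt2
    filt = {"a": lo, "d": hi}

    def analyze(arr: np.ndarray, axis: int, f: np.ndarray) -> np.ndarray:
        arr = np.moveaxis(arr, axis, 0)
        n = arr.shape[0]
        out = np.empty((n // 2,) + arr.shape[1:])
        for i in range(n // 2):
            out[i] = f[0] * arr[2 * i] + f[1] * arr[2 * i + 1]
        return np.moveaxis(out, 0, axis)

    bands = {}
    for code in itertools.product("ad", repeat=3):
        arr = image.astype(float)
        for axis, c in enumerate(code):
            arr = analyze(arr, axis, filt[c])
        bands["".join(code)] = arr
    return bands


def auc_pairs_oracle(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair comparison."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def ranksum_exact_oracle(a, b) -> float:
    """Two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(list(a) + list(b))
    ranks = {}
    # average ranks for ties
    vals = np.array(pooled, dtype=float)
    order = np.argsort(vals, kind="stable")
    rk = np.empty(len(vals))
    i = 0
    while i < len(vals):
        j = i
        while j + 1 < len(vals) and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        rk[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    na = len(a)
    # observed statistic: sum of ranks of group a (match values in order)
    remaining = list(rk)
    obs = 0.0
    vals_list = list(vals)
    for x in a:
        idx = vals_list.index(x)
        obs += remaining[idx]
        vals_list[idx] = None
    mean_w = na * (len(vals) + 1) / 2.0
    count = 0
    extreme = 0
    for combo in itertools.combinations(range(len(vals)), na):
        w = sum(rk[i] for i in combo)
        count += 1
        if abs(w - mean_w) >= abs(obs - mean_w) - 1e-12:
            extreme += 1
    return extreme / count
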