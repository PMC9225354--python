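"""Independent brute-force oracles used by the test suite.

Each oracle implements the reference definition of an operation as directly
as possible (explicit loops, breadth-first search, exhaustive enumeration)
and deliberately shares no code with the package implementation.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def truncated_gaussian_kernel_1d(sigma: float, support: int) -> np.ndarray:
    x = np.arange(-support, support + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def direct_gaussian_convolution(vol: np.ndarray, sigma: float, support: int) -> np.ndarray:
    """Triple-loop separable-kernel convolution with symmetric (mirror)
    border handling, evaluated via an explicitly padded volume."""
    k1 = truncated_gaussian_kernel_1d(sigma, support)
    k3 = np.einsum("i,j,k->ijk", k1, k1, k1)
    s = support
    padded = np.pad(vol, s, mode="symmetric")
    out = np.empty_like(vol, dtype=float)
    n = 2 * s + 1
    for i in range(vol.shape[0]):
        for j in range(vol.shape[1]):
            for k in range(vol.shape[2]):
                window = padded[i : i + n, j : j + n, k : k + n]
                out[i, j, k] = float(np.sum(window * k3))
    return out


def bfs_flood_fill(eligible: np.ndarray, seeds: np.ndarray,
                   connectivity: int = 6) -> np.ndarray:
    """Breadth-first flood fill of band-eligible voxels from seed voxels."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    visited = np.zeros_like(eligible, dtype=bool)
    q: deque = deque()
    for idx in zip(*np.nonzero(seeds & eligible)):
        visited[idx] = True
        q.append(idx)
    shape = eligible.shape
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in offsets:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                if eligible[nz, ny, nx] and not visited[nz, ny, nx]:
                    visited[nz, ny, nx] = True
                    q.append((nz, ny, nx))
    return visited


def iterated_min_filter_erosion(mask: np.ndarray, rounds: int) -> np.ndarray:
    """Binary erosion as an iterated 6-neighbourhood minimum filter."""
    out = mask.astype(np.uint8)
    shape = mask.shape
    for _ in range(rounds):
        nxt = np.zeros_like(out)
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if not out[z, y, x]:
                        continue
                    ok = True
                    for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        nz, ny, nx = z + dz, y + dy, x + dx
                        if not (0 <= nz < shape[0] and 0 <= ny < shape[1]
                                and 0 <= nx < shape[2]) or not out[nz, ny, nx]:
                            ok = False
                            break
                    nxt[z, y, x] = ok
        out = nxt
    return out.astype(bool)


def loop_threshold_count(values: np.ndarray, lo: float, hi: float) -> int:
    count = 0
    for v in values.ravel():
        if lo <= v <= hi:
            count += 1
    return count


def loop_positive_pixel_count(mask: np.ndarray) -> int:
    count = 0
    for row in mask:
        for px in row:
            if px:
                count += 1
    return count


def exhaustive_permutation_t_pvalue(a, b) -> float:
    """Two-tailed permutation p-value over all C(n1+n2, n1) relabelings,
    using |t| (pooled) as the statistic; ties count as at least as extreme."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = a.size

    def tstat(x, y):
        df = x.size + y.size - 2
        sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
        return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / x.size + 1 / y.size))

    t_obs = abs(tstat(a, b))
    n_extreme = 0
    total = 0
    for idx in combinations(range(pooled.size), n1):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(idx)] = True
        t = abs(tstat(pooled[sel], pooled[~sel]))
        total += 1
        if t >= t_obs - 1e-12:
            n_extreme += 1
    return n_extreme / total
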