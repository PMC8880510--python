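"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (triple loops, grid searches,
permutations) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

# ---------------------------------------------------------------- texture

DIRECTIONS_13 = [
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and d > (0, 0, 0)
]
assert len(DIRECTIONS_13) == 13


def brute_glrlm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length matrix r(i, j) summed over the 13 unique 3D directions.

    A run is a maximal sequence of in-mask voxels of equal level along a
    direction; every voxel of the grid is tried as a potential run start.
    """
    shape = levels.shape
    max_run = max(shape)
    r = np.zeros((n_levels, max_run), dtype=int)

    def inside(p):
        return all(0 <= p[a] < shape[a] for a in range(3)) and mask[p]

    for d in DIRECTIONS_13:
        for start in np.ndindex(shape):
            if not inside(start):
                continue
            prev = (start[0] - d[0], start[1] - d[1], start[2] - d[2])
            if inside(prev) and levels[prev] == levels[start]:
                continue  # not a run start
            length = 1
            cur = start
            while True:
                nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if inside(nxt) and levels[nxt] == levels[start]:
                    length += 1
                    cur = nxt
                else:
                    break
            r[levels[start] - 1, length - 1] += 1
    return r


def brute_glszm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix via flood fill over 26-connected equal-level zones."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones = []
    offsets = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for start in np.ndindex(shape):
        if not mask[start] or visited[start]:
            continue
        lev = levels[start]
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for d in offsets:
                q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if (
                    all(0 <= q[a] < shape[a] for a in range(3))
                    and mask[q]
                    and not visited[q]
                    and levels[q] == lev
                ):
                    visited[q] = True
                    stack.append(q)
        zones.append((lev, size))
    max_size = max(s for _, s in zones)
    z = np.zeros((n_levels, max_size), dtype=int)
    for lev, size in zones:
        z[lev - 1, size - 1] += 1
    return z


def brute_glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts at distance 1, 13 directions merged."""
    shape = levels.shape
    c = np.zeros((n_levels, n_levels), dtype=int)
    for d in DIRECTIONS_13:
        for p in np.ndindex(shape):
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if not all(0 <= q[a] < shape[a] for a in range(3)):
                continue
            if mask[p] and mask[q]:
                c[levels[p] - 1, levels[q] - 1] += 1
                c[levels[q] - 1, levels[p] - 1] += 1
    return c


def brute_sre(rlm: np.ndarray) -> float:
    """Short Run Emphasis straight from its definition."""
    nr = rlm.sum()
    total = 0.0
    for i in range(rlm.shape[0]):
        for j in range(rlm.shape[1]):
            total += rlm[i, j] / (j + 1) ** 2
    return total / nr


def brute_dilate(mask: np.ndarray, connectivity6: bool = True) -> np.ndarray:
    """One-step binary dilation by explicit neighbourhood expansion."""
    if connectivity6:
        offsets = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ]
    else:
        offsets = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    out = mask.copy()
    shape = mask.shape
    for p in zip(*np.where(mask)):
        for d in offsets:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if all(0 <= q[a] < shape[a] for a in range(3)):
                out[q] = True
    return out


def brute_ring(mask: np.ndarray, spacing, thickness_mm: float) -> np.ndarray:
    """Peritumoral shell from explicit voxel-to-voxel distances."""
    coords = np.argwhere(mask) * np.asarray(spacing)
    ring = np.zeros(mask.shape, dtype=bool)
    for p in np.ndindex(mask.shape):
        if mask[p]:
            continue
        pt = np.asarray(p) * np.asarray(spacing)
        dmin = np.sqrt(((coords - pt) ** 2).sum(axis=1)).min()
        if dmin <= thickness_mm:
            ring[p] = True
    return ring


# ---------------------------------------------------------------- survival


def cox_loglik_1d(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Log partial likelihood for one covariate, no ties assumed."""
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def grid_search_cox_1d(x, time, event, lo=-15.0, hi=15.0, tol=1e-6) -> float:
    """Golden-section refinement of a coarse grid maximiser of the 1-D
    partial likelihood; independent of any Newton-Raphson machinery."""
    grid = np.linspace(lo, hi, 6001)
    vals = [cox_loglik_1d(b, x, time, event) for b in grid]
    k = int(np.argmax(vals))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    gr = (np.sqrt(5) - 1) / 2
    while b - a > tol:
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        if cox_loglik_1d(c, x, time, event) >= cox_loglik_1d(d, x, time, event):
            b = d
        else:
            a = c
    return 0.5 * (a + b)


def logrank_statistic(time, event, group) -> float:
    """Plain-loop log-rank chi-square for the permutation oracle."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group, bool)
    o_minus_e = 0.0
    v = 0.0
    for t in np.unique(time[event]):
        at = time >= t
        nj = at.sum()
        n1 = (at & group).sum()
        dj = (event & (time == t)).sum()
        d1 = (event & (time == t) & group).sum()
        o_minus_e += d1 - dj * n1 / nj
        if nj > 1:
            v += dj * (n1 / nj) * (1 - n1 / nj) * (nj - dj) / (nj - 1)
    if v == 0:
        return 0.0
    return o_minus_e**2 / v


def permutation_logrank_p(time, event, group, n_perm: int, seed: int) -> float:
    """Permutation p-value of the log-rank statistic under label exchange."""
    rng = np.random.default_rng(seed)
    obs = logrank_statistic(time, event, group)
    group = np.asarray(group, bool)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(group)
        if logrank_statistic(time, event, perm) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def permutation_logrank_p_fast(time, event, group, n_perm: int, seed: int) -> float:
    """Vectorised permutation p-value of the log-rank statistic.

    Same null distribution as :func:`permutation_logrank_p` (checked in
    the suite), but computes the statistic for all permutations at once
    so 1e5 permutations are feasible.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group, bool)
    rng = np.random.default_rng(seed)
    obs = logrank_statistic(time, event, group)
    ev_times = np.unique(time[event])
    A = (time[None, :] >= ev_times[:, None]).astype(float)  # K x n at-risk
    D = (event[None, :] & (time[None, :] == ev_times[:, None])).astype(float)
    nj = A.sum(axis=1)
    dj = D.sum(axis=1)
    # permuted labels: P x n
    L = np.empty((n_perm, len(time)))
    base = group.astype(float)
    for i in range(n_perm):
        L[i] = rng.permutation(base)
    n1 = L @ A.T  # P x K
    d1 = L @ D.T
    ome = (d1 - dj * n1 / nj).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dj * (n1 / nj) * (1 - n1 / nj) * (nj - dj) / np.maximum(nj - 1, 1)
    var = np.where(nj > 1, var, 0.0)
    v = var.sum(axis=1)
    stat = np.where(v > 0, ome**2 / np.maximum(v, 1e-300), 0.0)
    count = int((stat >= obs - 1e-12).sum())
    return (count + 1) / (n_perm + 1)


def stepup_bh(p: np.ndarray) -> np.ndarray:
    """Textbook BH step-up: p_(k) * m / k with running minimum from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation, population (1/n) moments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    vx = ((x - mx) ** 2).mean()
    vy = ((y - my) ** 2).mean()
    cov = ((x - mx) * (y - my)).mean()
    return 2 * cov / (vx + vy + (mx - my) ** 2)
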