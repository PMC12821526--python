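"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the rule definitions, without
reusing any package internals, so that agreement with the package is a
meaningful check.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np

NEIGHBOURS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def brute_force_maxima(grid, mask, noise_tolerance, intensity_threshold,
                       min_distance_xy, min_distance_z, voxel_size,
                       reference=None):
    """Exhaustive seed detection following the prominence rule literally.

    A candidate is a mask voxel that is >= all its 26-neighbours inside the
    mask and whose threshold image value is >= the intensity threshold.  It
    is suppressed if the connected region of {value > candidate - tol}
    (within the mask) that contains it also contains another *candidate*
    that is higher in the total order (greater value, or equal value at
    smaller flat index).  Survivors undergo greedy minimum-distance
    suppression, brightest (then lexicographically smallest) first.
    Returns a sorted list of (z, y, x) positions.
    """
    grid = np.asarray(grid, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    ref = grid if reference is None else np.asarray(reference, dtype=float)
    nz, ny, nx = grid.shape

    def in_bounds(p):
        return 0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx

    def flat(p):
        return (p[0] * ny + p[1]) * nx + p[2]

    candidates = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or ref[z, y, x] < intensity_threshold:
                    continue
                v = grid[z, y, x]
                is_max = True
                for off in NEIGHBOURS_26:
                    q = (z + off[0], y + off[1], x + off[2])
                    if in_bounds(q) and mask[q] and grid[q] > v:
                        is_max = False
                        break
                if is_max:
                    candidates.append((z, y, x))

    cand_set = set(candidates)
    survivors = []
    for m in candidates:
        v = grid[m]
        floor = v - noise_tolerance
        seen = {m}
        queue = deque([m])
        suppressed = False
        while queue and not suppressed:
            p = queue.popleft()
            for off in NEIGHBOURS_26:
                q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
                if q in seen or not in_bounds(q) or not mask[q]:
                    continue
                if grid[q] <= floor:
                    continue
                if q in cand_set and (
                    grid[q] > v or (grid[q] == v and flat(q) < flat(m))
                ):
                    suppressed = True
                    break
                seen.add(q)
                queue.append(q)
        if not suppressed:
            survivors.append(m)

    survivors.sort(key=lambda p: (-grid[p], flat(p)))
    dz, dy, dx = voxel_size
    kept = []
    for p in survivors:
        close = False
        for q in kept:
            d_xy = np.hypot((p[1] - q[1]) * dy, (p[2] - q[2]) * dx)
            d_z = abs(p[0] - q[0]) * dz
            if d_xy < min_distance_xy and d_z < min_distance_z:
                close = True
                break
        if not close:
            kept.append(p)
    return sorted(kept)


def brute_force_u(x, y):
    """Mann-Whitney U by literal pair counting."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def brute_force_mw_pvalue(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every split of the
    pooled sample (feasible for small n)."""
    x = list(x)
    y = list(y)
    pooled = x + y
    n1 = len(x)
    u_obs = brute_force_u(x, y)
    centre = n1 * len(y) / 2.0
    dev = abs(u_obs - centre) - 1e-9
    hits = total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        sel = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in sel]
        total += 1
        if abs(brute_force_u(xs, ys) - centre) >= dev:
            hits += 1
    return hits / total


def brute_force_jt(groups):
    s = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            s += brute_force_u(groups[j], groups[i])
    return s


def brute_force_jt_pvalue(groups):
    """Exact two-sided JT p (deviation around the exact null mean) by full
    enumeration of group assignments."""
    pooled = [v for g in groups for v in g]
    ns = [len(g) for g in groups]
    n = len(pooled)
    mu = (n ** 2 - sum(k ** 2 for k in ns)) / 4.0
    obs = brute_force_jt(groups)
    dev = abs(obs - mu) - 1e-9
    hits = total = 0

    def rec(remaining, gi, built):
        nonlocal hits, total
        if gi == len(ns) - 1:
            parts = built + [[pooled[i] for i in remaining]]
            total += 1
            if abs(brute_force_jt(parts) - mu) >= dev:
                hits += 1
            return
        for comb in combinations(remaining, ns[gi]):
            sel = set(comb)
            rest = tuple(i for i in remaining if i not in sel)
            rec(rest, gi + 1, built + [[pooled[i] for i in comb]])

    rec(tuple(range(n)), 0, [])
    return hits / total


def brute_force_tau_b(group_ranks, values):
    """Kendall tau-b by literal concordance counting."""
    g = list(group_ranks)
    v = list(values)
    n = len(g)
    conc = disc = tg = tv = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = int(g[i] > g[j]) - int(g[i] < g[j])
            b = int(v[i] > v[j]) - int(v[i] < v[j])
            if a == 0 and b == 0:
                tg += 1
                tv += 1
            elif a == 0:
                tg += 1
            elif b == 0:
                tv += 1
            elif a == b:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tg) * (n0 - tv))
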