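"""Independent brute-force oracles used to check the implementation.

These are deliberately naive: full correlation matrices, explicit BFS on an
adjacency list, textbook closed forms, and direct step-up enumeration. They
share no code with the package's vectorized implementations.
"""

from collections import deque

import numpy as np


def neighbor_list(shape, connectivity):
    """Spatial neighbour offsets via explicit squared-distance classification."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d2 = dx * dx + dy * dy + dz * dz
                if d2 == 0:
                    continue
                if (connectivity == 6 and d2 == 1) or (connectivity == 18 and d2 <= 2) or connectivity == 26:
                    offs.append((dx, dy, dz))
    return offs


def bfs_lfcd(data4d, mask, r_threshold, connectivity, include_seed=False):
    """Exhaustive lFCD oracle.

    For each seed: compute the full seed-vs-all correlation vector, threshold
    it, and breadth-first search the spatial-neighbour graph restricted to
    suprathreshold voxels, starting at the seed. The count of reached
    suprathreshold voxels (seed excluded unless ``include_seed``) is the lFCD.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = [tuple(c) for c in np.argwhere(mask)]
    full_corr = np.corrcoef(np.stack([data4d[c] for c in coords]))
    corr = {
        (a, b): full_corr[i, j]
        for i, a in enumerate(coords)
        for j, b in enumerate(coords)
        if i != j
    }
    offs = neighbor_list(mask.shape, connectivity)
    shape = mask.shape
    out = np.zeros(shape)
    for seed in coords:
        supra = {c for c in coords if c != seed and corr[(seed, c)] > r_threshold}
        supra.add(seed)
        reached = {seed}
        queue = deque([seed])
        while queue:
            cur = queue.popleft()
            for off in offs:
                nxt = tuple(np.add(cur, off))
                if all(0 <= nxt[i] < shape[i] for i in range(3)) and nxt in supra and nxt not in reached:
                    reached.add(nxt)
                    queue.append(nxt)
        out[seed] = len(reached) - (0 if include_seed else 1)
    return out


def bh_stepup(p_values, q):
    """Direct Benjamini–Hochberg step-up enumeration."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i / m * q:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def pooled_t(a, b):
    """Two-sample pooled-variance Student t (a minus b), textbook form."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    s2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
    return (a.mean() - b.mean()) / np.sqrt(s2 * (1 / n1 + 1 / n2))


def pearson_r(x, y):
    """Pearson correlation from the covariance/variance table."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
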