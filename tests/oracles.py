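"""Independent brute-force reference implementations used as oracles.

These deliberately share no code with the package: runs are enumerated by
walking every grid line voxel by voxel, zones by breadth-first flood
fill, NGTDM entries by an explicit per-voxel neighborhood loop, and Ward
merges by recomputing the exact error-sum-of-squares increase of every
candidate merge from cluster members.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_run_length_matrix(levels: np.ndarray, direction) -> dict:
    """{(gray level, run length): count} by walking every maximal line."""
    lv = np.asarray(levels)
    shape = lv.shape
    d = tuple(direction)
    counts: dict[tuple[int, int], int] = {}

    def in_grid(p):
        return all(0 <= p[i] < shape[i] for i in range(3))

    for x in np.ndindex(shape):
        prev = tuple(x[i] - d[i] for i in range(3))
        if in_grid(prev):
            continue  # not a line start
        # walk the whole line, splitting runs on level changes / level 0
        pos = x
        line = []
        while in_grid(pos):
            line.append(lv[pos])
            pos = tuple(pos[i] + d[i] for i in range(3))
        i = 0
        while i < len(line):
            g = line[i]
            j = i
            while j < len(line) and line[j] == g:
                j += 1
            if g > 0:
                counts[(int(g), j - i)] = counts.get((int(g), j - i), 0) + 1
            i = j
    return counts


def brute_zones(levels: np.ndarray) -> dict:
    """{(gray level, zone size): count} by BFS flood fill, 26-connectivity."""
    lv = np.asarray(levels)
    shape = lv.shape
    seen = np.zeros(shape, dtype=bool)
    nbrs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    counts: dict[tuple[int, int], int] = {}
    for start in np.ndindex(shape):
        if lv[start] == 0 or seen[start]:
            continue
        g = lv[start]
        size = 0
        q = deque([start])
        seen[start] = True
        while q:
            p = q.popleft()
            size += 1
            for d in nbrs:
                np_ = tuple(p[i] + d[i] for i in range(3))
                if all(0 <= np_[i] < shape[i] for i in range(3)):
                    if not seen[np_] and lv[np_] == g:
                        seen[np_] = True
                        q.append(np_)
        counts[(int(g), size)] = counts.get((int(g), size), 0) + 1
    return counts


def brute_ngtdm(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) by explicit per-voxel 26-neighborhood means."""
    lv = np.asarray(levels, dtype=float)
    shape = lv.shape
    ng = int(lv.max())
    n = np.zeros(ng)
    s = np.zeros(ng)
    for x in np.ndindex(shape):
        if lv[x] == 0:
            continue
        vals = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    p = (x[0] + dx, x[1] + dy, x[2] + dz)
                    if all(0 <= p[i] < shape[i] for i in range(3)) and lv[p] > 0:
                        vals.append(lv[p])
        if not vals:
            continue
        g = int(lv[x])
        n[g - 1] += 1
        s[g - 1] += abs(lv[x] - np.mean(vals))
    return n, s


def brute_ward_labels(x: np.ndarray, k: int) -> np.ndarray:
    """Greedy Ward agglomeration computing the exact ESS increase
    n_a n_b / (n_a + n_b) * ||c_a - c_b||^2 for every candidate merge."""
    x = np.asarray(x, dtype=float)
    clusters = [[i] for i in range(x.shape[0])]
    while len(clusters) > k:
        best = None
        best_cost = np.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = x[clusters[a]].mean(axis=0)
                cb = x[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                cost = na * nb / (na + nb) * ((ca - cb) ** 2).sum()
                if cost < best_cost:
                    best_cost = cost
                    best = (a, b)
        a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(x.shape[0], dtype=int)
    for li, members in enumerate(clusters):
        labels[members] = li + 1
    return labels


def two_point_auc(p_high_given_a: float, p_high_given_b: float) -> float:
    """Closed-form ROC area for a binary predictor with balanced groups."""
    tpr = p_high_given_a / (p_high_given_a + p_high_given_b)
    fpr = (1 - p_high_given_a) / ((1 - p_high_given_a) + (1 - p_high_given_b))
    return 0.5 * (1 + tpr - fpr)
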