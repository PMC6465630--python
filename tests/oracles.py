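"""Independent brute-force oracles used by the tests.

Everything here is written as plain Python loops over voxels/matrix cells,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------

def glcm_pairs(level_map, mask, direction):
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    ng = int(level_map[mask].max())
    mat = np.zeros((ng, ng))
    nx, ny, nz = level_map.shape
    dx, dy, dz = direction
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                q = (x + dx, y + dy, z + dz)
                if all(0 <= q[a] < level_map.shape[a] for a in range(3)) and mask[q]:
                    i = level_map[x, y, z] - 1
                    j = level_map[q] - 1
                    mat[i, j] += 1
                    mat[j, i] += 1
    return mat


def glszm_zones(level_map, mask):
    """(level, size) of every 26-connected equal-level zone, by BFS."""
    visited = np.zeros_like(mask, dtype=bool)
    zones = []
    coords = list(zip(*np.nonzero(mask)))
    for start in coords:
        if visited[start]:
            continue
        lev = level_map[start]
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        if dx == dy == dz == 0:
                            continue
                        q = (p[0] + dx, p[1] + dy, p[2] + dz)
                        if all(0 <= q[a] < mask.shape[a] for a in range(3)) \
                                and mask[q] and not visited[q] \
                                and level_map[q] == lev:
                            visited[q] = True
                            stack.append(q)
        zones.append((int(lev), size))
    return zones


def glrlm_runs(level_map, mask, direction):
    """(level, length) of every maximal run along ``direction``."""
    runs = []
    nx, ny, nz = level_map.shape
    d = direction
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                p = (x, y, z)
                if not mask[p]:
                    continue
                prev = (x - d[0], y - d[1], z - d[2])
                if all(0 <= prev[a] < level_map.shape[a] for a in range(3)) \
                        and mask[prev] and level_map[prev] == level_map[p]:
                    continue  # not a run start
                length = 1
                q = (x + d[0], y + d[1], z + d[2])
                while all(0 <= q[a] < level_map.shape[a] for a in range(3)) \
                        and mask[q] and level_map[q] == level_map[p]:
                    length += 1
                    q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
                runs.append((int(level_map[p]), length))
    return runs


def ngtdm_counts(level_map, mask, ng):
    """(n_i, s_i, N) by explicit per-voxel neighborhood loops."""
    n = np.zeros(ng)
    s = np.zeros(ng)
    total = 0
    for p in zip(*np.nonzero(mask)):
        neigh = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    q = (p[0] + dx, p[1] + dy, p[2] + dz)
                    if all(0 <= q[a] < mask.shape[a] for a in range(3)) and mask[q]:
                        neigh.append(level_map[q])
        if not neigh:
            continue
        lev = int(level_map[p])
        n[lev - 1] += 1
        s[lev - 1] += abs(lev - sum(neigh) / len(neigh))
        total += 1
    return n, s, total


# ---------------------------------------------------------------------------
# survival statistics
# ---------------------------------------------------------------------------

def logrank_chi2(time_a, event_a, time_b, event_b):
    """Observed-minus-expected log-rank statistic over event-time risk sets."""
    times = sorted(set(list(time_a[event_a == 1]) + list(time_b[event_b == 1])))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = np.sum(time_a >= t)
        n2 = np.sum(time_b >= t)
        d1 = np.sum((time_a == t) & (event_a == 1))
        d2 = np.sum((time_b == t) & (event_b == 1))
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return o_minus_e**2 / var


def harrell_c_pairs(marker, time, event):
    """Concordance by exhaustive usable-pair enumeration (risk convention)."""
    conc = 0.0
    usable = 0
    n = len(marker)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                usable += 1
                if marker[i] > marker[j]:
                    conc += 1.0
                elif marker[i] == marker[j]:
                    conc += 0.5
    return conc / usable


def delong_variance(a, b, label):
    """Variance of AUC_a - AUC_b via explicit placement values."""
    pos_a = a[label == 1]; neg_a = a[label == 0]
    pos_b = b[label == 1]; neg_b = b[label == 0]
    m, n = len(pos_a), len(neg_a)

    def placements(pos, neg):
        v10 = np.array([np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                                 for q in neg]) for p in pos])
        v01 = np.array([np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                                 for p in pos]) for q in neg])
        return v10, v01

    va10, va01 = placements(pos_a, neg_a)
    vb10, vb01 = placements(pos_b, neg_b)
    s10 = np.cov(np.vstack([va10, vb10]))
    s01 = np.cov(np.vstack([va01, vb01]))
    return (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + \
           (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n


def icc21_anova(a, b):
    """ICC(2,1) from the two-way ANOVA mean squares, written out by hand."""
    n = len(a)
    k = 2
    grand = (sum(a) + sum(b)) / (n * k)
    ms_rows = sum(k * ((ai + bi) / 2 - grand) ** 2 for ai, bi in zip(a, b)) / (n - 1)
    col_means = (sum(a) / n, sum(b) / n)
    ms_cols = sum(n * (c - grand) ** 2 for c in col_means) / (k - 1)
    ss_tot = sum((x - grand) ** 2 for x in list(a) + list(b))
    ss_rows = sum(k * ((ai + bi) / 2 - grand) ** 2 for ai, bi in zip(a, b))
    ss_cols = sum(n * (c - grand) ** 2 for c in col_means)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)
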