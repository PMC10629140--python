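"""Independent brute-force oracles for texture matrices and statistics.

Everything here is written as plain nested loops over voxels, deliberately
sharing no code with the vectorized implementations it checks.
"""

from __future__ import annotations

import numpy as np

DIRECTIONS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]

NEIGHBOURS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _inside(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def glcm_brute(levels, mask, ng, distance=1):
    shape = levels.shape
    out = np.zeros((len(DIRECTIONS), ng, ng))
    for k, d in enumerate(DIRECTIONS):
        m = np.zeros((ng, ng))
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if not mask[z, y, x]:
                        continue
                    w = (z + d[0] * distance, y + d[1] * distance, x + d[2] * distance)
                    if _inside(shape, w) and mask[w]:
                        m[levels[z, y, x] - 1, levels[w] - 1] += 1
        out[k] = m + m.T
    return out


def glrlm_brute(levels, mask, ng):
    shape = levels.shape
    runs_per_dir = []
    max_len = 1
    for d in DIRECTIONS:
        runs = []
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    v = (z, y, x)
                    if not mask[v]:
                        continue
                    prev = (z - d[0], y - d[1], x - d[2])
                    if (
                        _inside(shape, prev)
                        and mask[prev]
                        and levels[prev] == levels[v]
                    ):
                        continue  # not a run head
                    length = 1
                    w = (z + d[0], y + d[1], x + d[2])
                    while _inside(shape, w) and mask[w] and levels[w] == levels[v]:
                        length += 1
                        w = (w[0] + d[0], w[1] + d[1], w[2] + d[2])
                    runs.append((levels[v], length))
                    max_len = max(max_len, length)
        runs_per_dir.append(runs)
    out = np.zeros((len(DIRECTIONS), ng, max_len))
    for k, runs in enumerate(runs_per_dir):
        for g, length in runs:
            out[k, g - 1, length - 1] += 1
    return out


def glszm_brute(levels, mask, ng):
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                g = levels[z, y, x]
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    v = stack.pop()
                    size += 1
                    for d in NEIGHBOURS:
                        w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                        if (
                            _inside(shape, w)
                            and mask[w]
                            and not seen[w]
                            and levels[w] == g
                        ):
                            seen[w] = True
                            stack.append(w)
                zones.append((g, size))
    max_size = max((s for _, s in zones), default=1)
    out = np.zeros((ng, max_size))
    for g, s in zones:
        out[g - 1, s - 1] += 1
    return out


def gldm_brute(levels, mask, ng, alpha=0.0):
    shape = levels.shape
    deps = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                count = 0
                for d in NEIGHBOURS:
                    w = (z + d[0], y + d[1], x + d[2])
                    if (
                        _inside(shape, w)
                        and mask[w]
                        and abs(int(levels[w]) - int(levels[z, y, x])) <= alpha
                    ):
                        count += 1
                deps.append((levels[z, y, x], count + 1))
    nd = max(s for _, s in deps)
    out = np.zeros((ng, nd))
    for g, s in deps:
        out[g - 1, s - 1] += 1
    return out


def ngtdm_brute(levels, mask, ng):
    shape = levels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    nvp = 0
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                nbrs = []
                for d in NEIGHBOURS:
                    w = (z + d[0], y + d[1], x + d[2])
                    if _inside(shape, w) and mask[w]:
                        nbrs.append(levels[w])
                if not nbrs:
                    continue
                g = levels[z, y, x]
                n[g - 1] += 1
                s[g - 1] += abs(g - sum(nbrs) / len(nbrs))
                nvp += 1
    out = np.zeros((ng, 3))
    out[:, 0] = n
    if nvp:
        out[:, 1] = n / nvp
    out[:, 2] = s
    return out


def ccc_brute(x, y):
    """Lin's CCC evaluated term by term with 1/n moments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2 * cov / (vx + vy + (mx - my) ** 2)


def pad_to_match(a, b):
    """Zero-pad the last axis of two matrices to a common width."""
    w = max(a.shape[-1], b.shape[-1])
    pa = np.zeros(a.shape[:-1] + (w,))
    pb = np.zeros(b.shape[:-1] + (w,))
    pa[..., : a.shape[-1]] = a
    pb[..., : b.shape[-1]] = b
    return pa, pb
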