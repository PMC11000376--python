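"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, flood fill, pair
enumeration) and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def bf_glcm(labels: np.ndarray, n_levels: int, offset) -> np.ndarray:
    """Exhaustive symmetric co-occurrence counts for one offset (0 = outside)."""
    mat = np.zeros((n_levels, n_levels))
    nz, ny, nx = labels.shape
    dz, dy, dx = offset
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = labels[z, y, x]
                z2, y2, x2 = z + dz, y + dy, x + dx
                if a == 0 or not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                b = labels[z2, y2, x2]
                if b == 0:
                    continue
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
    return mat


def bf_glrlm(labels: np.ndarray, n_levels: int, offset) -> dict[tuple[int, int], int]:
    """Run counts {(level, length): count} along one direction."""
    nz, ny, nx = labels.shape
    dz, dy, dx = offset
    runs: dict[tuple[int, int], int] = {}
    visited = set()
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                pz, py, px = z - dz, y - dy, x - dx
                if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx:
                    continue  # not a line start
                seq = []
                cz, cy, cx = z, y, x
                while 0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx:
                    seq.append(int(labels[cz, cy, cx]))
                    cz, cy, cx = cz + dz, cy + dy, cx + dx
                i = 0
                while i < len(seq):
                    if seq[i] == 0:
                        i += 1
                        continue
                    j = i
                    while j < len(seq) and seq[j] == seq[i]:
                        j += 1
                    runs[(seq[i], j - i)] = runs.get((seq[i], j - i), 0) + 1
                    i = j
    del visited
    return runs


def bf_glszm(labels: np.ndarray) -> dict[tuple[int, int], int]:
    """Zone counts {(level, size): count} by 26-connected flood fill."""
    nz, ny, nx = labels.shape
    seen = np.zeros(labels.shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    nbrs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if labels[z, y, x] == 0 or seen[z, y, x]:
                    continue
                lv = labels[z, y, x]
                stack, size = [(z, y, x)], 0
                seen[z, y, x] = True
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for a, b, c in nbrs:
                        z2, y2, x2 = cz + a, cy + b, cx + c
                        if (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx
                                and not seen[z2, y2, x2] and labels[z2, y2, x2] == lv):
                            seen[z2, y2, x2] = True
                            stack.append((z2, y2, x2))
                zones[(int(lv), size)] = zones.get((int(lv), size), 0) + 1
    return zones


def bf_ngtdm(labels: np.ndarray, n_levels: int):
    """(s, p, n_voxels) by explicit neighbourhood averaging."""
    nz, ny, nx = labels.shape
    s = np.zeros(n_levels)
    counts = np.zeros(n_levels)
    n_vox = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                lv = labels[z, y, x]
                if lv == 0:
                    continue
                n_vox += 1
                counts[lv - 1] += 1
                nb = []
                for a in (-1, 0, 1):
                    for b in (-1, 0, 1):
                        for c in (-1, 0, 1):
                            if (a, b, c) == (0, 0, 0):
                                continue
                            z2, y2, x2 = z + a, y + b, x + c
                            if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx:
                                if labels[z2, y2, x2] > 0:
                                    nb.append(labels[z2, y2, x2])
                if nb:
                    s[lv - 1] += abs(lv - float(np.mean(nb)))
    p = counts / n_vox if n_vox else counts
    return s, p, n_vox


def bf_auc(y, scores) -> float:
    """AUC by exhaustive concordant/discordant pair counting."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = conc = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                conc += 1
            elif sp == sn:
                conc += 0.5
    return conc / total


def bf_lstsq(t, v, degree) -> np.ndarray:
    """Polynomial LS coefficients (highest power first) via normal equations."""
    t = np.asarray(t, dtype=float)
    A = np.vander(t, degree + 1)
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(v, dtype=float))
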