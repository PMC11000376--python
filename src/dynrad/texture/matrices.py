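"""Gray-level texture matrices on 3D ROIs.

All four classical 3D texture matrices are built strictly inside the ROI:
voxels outside the mask never enter a pair, run, zone or neighbourhood.
GLCM and GLRLM are direction-dependent and are computed per offset over the
13 unique 3D directions at Chebyshev distance 1; GLSZM and NGTDM are
direction-free (26-connectivity).

The ROI is represented as an integer label volume where 0 marks out-of-ROI
voxels and in-ROI voxels carry gray levels 1..n_levels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# 13 unique direction offsets (dz, dy, dx): one of each antipodal pair.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

assert len(DIRECTIONS_13) == 13

__all__ = [
    "DIRECTIONS_13",
    "glcm",
    "glcm_all_directions",
    "glrlm",
    "glrlm_all_directions",
    "glszm",
    "ngtdm",
]


def _shifted_views(label_vol: np.ndarray, offset: tuple[int, int, int]):
    """Paired views of the volume and the volume shifted by ``offset``."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, label_vol.shape):
        if d > 0:
            sl_a.append(slice(0, n - d)), sl_b.append(slice(d, n))
        elif d < 0:
            sl_a.append(slice(-d, n)), sl_b.append(slice(0, n + d))
        else:
            sl_a.append(slice(None)), sl_b.append(slice(None))
    return label_vol[tuple(sl_a)], label_vol[tuple(sl_b)]


def glcm(label_vol: np.ndarray, n_levels: int, offset: tuple[int, int, int],
         normalize: bool = True) -> np.ndarray:
    """Symmetric gray-level co-occurrence matrix for one direction offset.

    Counts in-ROI voxel pairs (v, v+offset); symmetrised by adding the
    transpose, then normalised to sum 1 (unless ``normalize=False``).
    A direction with no valid pair returns an all-zero matrix.
    """
    a, b = _shifted_views(label_vol, offset)
    ok = (a > 0) & (b > 0)
    av, bv = a[ok] - 1, b[ok] - 1
    mat = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(mat, (av, bv), 1.0)
    mat = mat + mat.T
    if normalize and mat.sum() > 0:
        mat /= mat.sum()
    return mat


def glcm_all_directions(label_vol: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Normalised GLCMs for the 13 unique distance-1 directions.

    Directions with no valid pair are dropped. A single-voxel ROI (no pairs
    in any direction) degenerates to one matrix with all mass on the voxel's
    own (level, level) cell — a documented convention, not an error.
    """
    mats = [glcm(label_vol, n_levels, off) for off in DIRECTIONS_13]
    mats = [m for m in mats if m.sum() > 0]
    if not mats:
        lv = int(label_vol[label_vol > 0][0]) - 1
        m = np.zeros((n_levels, n_levels))
        m[lv, lv] = 1.0
        mats = [m]
    return mats


def glrlm(label_vol: np.ndarray, n_levels: int,
          offset: tuple[int, int, int]) -> np.ndarray:
    """Gray-level run-length matrix for one direction.

    Entry (i, l-1) counts maximal runs of ``l`` consecutive in-ROI voxels of
    level ``i+1`` along ``offset``; out-of-ROI voxels break runs. The matrix
    has max-run-length columns equal to the longest possible run.
    """
    shape = label_vol.shape
    max_len = int(np.ceil(np.sqrt(sum((d * n) ** 2 for d, n in zip(offset, shape))))) + 1
    mat = np.zeros((n_levels, max(max_len, 1)), dtype=np.float64)
    dz, dy, dx = offset
    # starting voxels: those with no in-grid predecessor along -offset
    idx = np.indices(shape)
    prev = [idx[0] - dz, idx[1] - dy, idx[2] - dx]
    in_grid = np.ones(shape, dtype=bool)
    for p, n in zip(prev, shape):
        in_grid &= (p >= 0) & (p < n)
    starts = np.argwhere(~in_grid)
    for z0, y0, x0 in starts:
        z, y, x = int(z0), int(y0), int(x0)
        cur_level, cur_len = 0, 0
        while 0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]:
            lv = int(label_vol[z, y, x])
            if lv == cur_level and lv > 0:
                cur_len += 1
            else:
                if cur_level > 0:
                    mat[cur_level - 1, cur_len - 1] += 1
                cur_level, cur_len = lv, 1
            z, y, x = z + dz, y + dy, x + dx
        if cur_level > 0:
            mat[cur_level - 1, cur_len - 1] += 1
    # trim empty tail columns for compactness
    nz = np.nonzero(mat.sum(axis=0))[0]
    if nz.size:
        mat = mat[:, : nz[-1] + 1]
    else:
        mat = mat[:, :1]
    return mat


def glrlm_all_directions(label_vol: np.ndarray, n_levels: int) -> list[np.ndarray]:
    return [glrlm(label_vol, n_levels, off) for off in DIRECTIONS_13]


def glszm(label_vol: np.ndarray, n_levels: int) -> np.ndarray:
    """Gray-level size-zone matrix (26-connected zones of equal level).

    Entry (i, s-1) counts connected zones of level ``i+1`` with ``s`` voxels.
    """
    structure = np.ones((3, 3, 3), dtype=bool)
    counts: dict[tuple[int, int], int] = {}
    max_size = 1
    for lv in np.unique(label_vol[label_vol > 0]):
        lab, n_zones = ndimage.label(label_vol == lv, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            counts[(int(lv), int(s))] = counts.get((int(lv), int(s)), 0) + 1
            max_size = max(max_size, int(s))
    mat = np.zeros((n_levels, max_size), dtype=np.float64)
    for (lv, s), c in counts.items():
        mat[lv - 1, s - 1] = c
    return mat


def ngtdm(label_vol: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Neighbourhood gray-tone difference matrix.

    For each in-ROI voxel, the average level of its in-ROI 26-neighbours is
    computed (voxels with no in-ROI neighbour contribute no difference).
    Returns (s, p, n_voxels): s[i] = summed |level - neighbourhood average|
    over voxels of level i+1, p[i] = fraction of ROI voxels of level i+1.
    """
    roi = label_vol > 0
    n_vox = int(roi.sum())
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    neigh_sum = ndimage.convolve(label_vol.astype(np.float64), kernel,
                                 mode="constant", cval=0.0)
    neigh_cnt = ndimage.convolve(roi.astype(np.float64), kernel,
                                 mode="constant", cval=0.0)
    s = np.zeros(n_levels)
    p = np.zeros(n_levels)
    has_neigh = roi & (neigh_cnt > 0)
    avg = np.zeros_like(neigh_sum)
    avg[has_neigh] = neigh_sum[has_neigh] / neigh_cnt[has_neigh]
    diffs = np.abs(label_vol - avg)
    for lv in range(1, n_levels + 1):
        sel = label_vol == lv
        p[lv - 1] = sel.sum() / n_vox if n_vox else 0.0
        s[lv - 1] = diffs[sel & has_neigh].sum()
    return s, p, n_vox
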