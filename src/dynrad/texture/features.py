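"""Texture feature formulas computed from the gray-level matrices.

The 53-feature texture roster is 22 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM.
GLCM and GLRLM features are averaged over the 13 unique 3D directions;
GLSZM and NGTDM are single-matrix. Entropies use log base 2.

Degenerate-input conventions (documented, never exceptions):
- constant ROI: GLCM marginal sigma = 0 -> both correlations and the
  information measures are returned as 0;
- NGTDM with zero total difference: coarseness is capped at 1e6 (flat
  region is maximally coarse), busyness and strength are 0;
- single-voxel ROI: run/zone matrices are 1x1 and the formulas evaluate
  on them directly.
"""

from __future__ import annotations

import numpy as np

from .matrices import (
    glcm_all_directions,
    glrlm_all_directions,
    glszm,
    ngtdm,
)

_EPS = np.finfo(np.float64).tiny
_COARSENESS_CAP = 1e6

GLCM_FEATURES = (
    "Autocorrelation",
    "Cluster prominence",
    "Cluster shade",
    "Cluster tendency",
    "Contrast",
    "Correlation1",
    "Correlation2",
    "Difference entropy",
    "Difference variance",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity1",
    "Homogeneity2",
    "IMC1",
    "IMC2",
    "Inverse difference normalized",
    "Inverse difference moment normalized",
    "Maximum probability",
    "Sum average",
    "Sum entropy",
    "Sum variance",
)

GLRLM_FEATURES = (
    "Short run emphasis",
    "Long run emphasis",
    "Gray-level nonuniformity",
    "Run-length nonuniformity",
    "Run percentage",
    "Low gray-level run emphasis",
    "High gray-level run emphasis",
    "Short run low gray-level emphasis",
    "Short run high gray-level emphasis",
    "Long run low gray-level emphasis",
    "Long run high gray-level emphasis",
    "Gray-level variance",
    "Run-length variance",
)

GLSZM_FEATURES = (
    "Small zone emphasis",
    "Large zone emphasis",
    "Gray-level nonuniformity (zone)",
    "Zone-size nonuniformity",
    "Zone percentage",
    "Low gray-level zone emphasis",
    "High gray-level zone emphasis",
    "Small zone low gray-level emphasis",
    "Small zone high gray-level emphasis",
    "Large zone low gray-level emphasis",
    "Large zone high gray-level emphasis",
    "Gray-level variance (zone)",
    "Zone-size variance",
)

NGTDM_FEATURES = (
    "Coarseness",
    "Contrast (NGTDM)",
    "Busyness",
    "Complexity",
    "Strength",
)

TEXTURE_FEATURE_NAMES = GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES + NGTDM_FEATURES
TEXTURE_FAMILY = (
    ("GLCM",) * len(GLCM_FEATURES)
    + ("GLRLM",) * len(GLRLM_FEATURES)
    + ("GLSZM",) * len(GLSZM_FEATURES)
    + ("NGTDM",) * len(NGTDM_FEATURES)
)

assert len(TEXTURE_FEATURE_NAMES) == 53


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 22 co-occurrence features of one normalised symmetric GLCM."""
    n = P.shape[0]
    levels = np.arange(1, n + 1, dtype=np.float64)
    i = levels[:, None]
    j = levels[None, :]
    px = P.sum(axis=1)
    mu_x = float((levels * px).sum())
    sigma_x = float(np.sqrt(((levels - mu_x) ** 2 * px).sum()))
    # symmetric matrix: y-marginal statistics equal the x ones
    mu_y, sigma_y = mu_x, sigma_x

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(n, dtype=np.float64)          # |i-j| = 0 .. n-1
    p_diff = np.zeros(n)
    k_sum = np.arange(2, 2 * n + 1, dtype=np.float64)  # i+j = 2 .. 2n
    p_sum = np.zeros(2 * n - 1)
    ii, jj = np.indices(P.shape)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())

    hxy = _entropy(P.ravel())
    px_py = px[:, None] * px[None, :]
    nzb = px_py > 0
    hxy1 = float(-(P[nzb] * np.log2(px_py[nzb])).sum())
    hxy2 = _entropy(px_py.ravel())
    hx = _entropy(px)

    if sigma_x > 0:
        corr1 = (float((i * j * P).sum()) - mu_x * mu_y) / (sigma_x * sigma_y)
        corr2 = float(((i - mu_x) * (j - mu_y) * P).sum()) / (sigma_x * sigma_y)
    else:
        corr1 = corr2 = 0.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return {
        "Autocorrelation": float((i * j * P).sum()),
        "Cluster prominence": float(((i + j - mu_x - mu_y) ** 4 * P).sum()),
        "Cluster shade": float(((i + j - mu_x - mu_y) ** 3 * P).sum()),
        "Cluster tendency": float(((i + j - mu_x - mu_y) ** 2 * P).sum()),
        "Contrast": float(((i - j) ** 2 * P).sum()),
        "Correlation1": corr1,
        "Correlation2": corr2,
        "Difference entropy": _entropy(p_diff),
        "Difference variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Dissimilarity": float((np.abs(i - j) * P).sum()),
        "Energy": float((P ** 2).sum()),
        "Entropy": hxy,
        "Homogeneity1": float((P / (1.0 + np.abs(i - j))).sum()),
        "Homogeneity2": float((P / (1.0 + (i - j) ** 2)).sum()),
        "IMC1": imc1,
        "IMC2": imc2,
        "Inverse difference normalized": float((P / (1.0 + np.abs(i - j) / n)).sum()),
        "Inverse difference moment normalized": float((P / (1.0 + (i - j) ** 2 / n ** 2)).sum()),
        "Maximum probability": float(P.max()),
        "Sum average": sa,
        "Sum entropy": _entropy(p_sum),
        "Sum variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
    }


def _size_weighted_features(mat: np.ndarray, n_voxels: int, names) -> dict[str, float]:
    """Shared run-length / size-zone formulas (rows = levels, cols = sizes)."""
    n_levels, max_size = mat.shape
    total = mat.sum()
    if total == 0:  # cannot happen for a non-empty ROI, kept as a guard
        return {name: 0.0 for name in names}
    i = np.arange(1, n_levels + 1, dtype=np.float64)[:, None]
    l = np.arange(1, max_size + 1, dtype=np.float64)[None, :]
    p = mat / total
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_l = float((l * p).sum())
    vals = (
        float((mat / l ** 2).sum() / total),
        float((mat * l ** 2).sum() / total),
        float((row ** 2).sum() / total),
        float((col ** 2).sum() / total),
        float(total / n_voxels),
        float((mat / i ** 2).sum() / total),
        float((mat * i ** 2).sum() / total),
        float((mat / (i ** 2 * l ** 2)).sum() / total),
        float((mat * i ** 2 / l ** 2).sum() / total),
        float((mat * l ** 2 / i ** 2).sum() / total),
        float((mat * i ** 2 * l ** 2).sum() / total),
        float(((i - mu_i) ** 2 * p).sum()),
        float(((l - mu_l) ** 2 * p).sum()),
    )
    return dict(zip(names, vals))


def glrlm_features_from_matrix(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _size_weighted_features(mat, n_voxels, GLRLM_FEATURES)


def glszm_features_from_matrix(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _size_weighted_features(mat, n_voxels, GLSZM_FEATURES)


def ngtdm_features_from_arrays(s: np.ndarray, p: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The five Amadasun-Ring neighbourhood difference features."""
    present = p > 0
    n_gp = int(present.sum())
    levels = np.arange(1, len(p) + 1, dtype=np.float64)
    ps = float((p * s).sum())

    coarseness = 1.0 / ps if ps > 0 else _COARSENESS_CAP
    coarseness = min(coarseness, _COARSENESS_CAP)

    if n_gp > 1:
        ipv = levels[present]
        ppv = p[present]
        diff2 = (ipv[:, None] - ipv[None, :]) ** 2
        contrast = float(
            (ppv[:, None] * ppv[None, :] * diff2).sum()
            / (n_gp * (n_gp - 1))
            * (s.sum() / n_voxels)
        )
        ipi = ipv * ppv
        denom_busy = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        sv = s[present]
        absdiff = np.abs(ipv[:, None] - ipv[None, :])
        complexity = float(
            (absdiff
             * (ppv[:, None] * sv[:, None] + ppv[None, :] * sv[None, :])
             / (ppv[:, None] + ppv[None, :])).sum() / n_voxels
        )
        s_tot = float(s.sum())
        strength = (
            float(((ppv[:, None] + ppv[None, :]) * diff2).sum()) / s_tot
            if s_tot > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast (NGTDM)": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def texture_features_from_labels(label_vol: np.ndarray, n_levels: int) -> dict[str, float]:
    """All 53 texture features of an ROI given as a gray-level label volume.

    GLCM and GLRLM feature values are the mean over the 13 directions.
    """
    # crop to the ROI bounding box: matrices only involve in-ROI voxels
    nz = np.argwhere(label_vol > 0)
    lo, hi = nz.min(axis=0), nz.max(axis=0) + 1
    label_vol = label_vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    n_voxels = int((label_vol > 0).sum())

    glcm_mats = glcm_all_directions(label_vol, n_levels)
    per_dir = [glcm_features(P) for P in glcm_mats]
    out: dict[str, float] = {
        name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_FEATURES
    }

    rl_mats = glrlm_all_directions(label_vol, n_levels)
    per_dir_rl = [glrlm_features_from_matrix(m, n_voxels) for m in rl_mats]
    out.update(
        {name: float(np.mean([d[name] for d in per_dir_rl])) for name in GLRLM_FEATURES}
    )

    out.update(glszm_features_from_matrix(glszm(label_vol, n_levels), n_voxels))
    out.update(ngtdm_features_from_arrays(*ngtdm(label_vol, n_levels)))
    return out
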