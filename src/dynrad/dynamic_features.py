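"""Dynamic radiomics features: 20 summaries of each static feature's
trajectory across the 4 contrast phases.

Given the series v = (v1..v4) of one static feature at times t = (t1..t4),
the 20 dynamic features are:

- integrated (3): mean, population variance, coefficient of variation sd/mean;
- discrete (6): per consecutive segment s = (i, i+1) the relative change
  rate RCR_s = |v_{i+1} - v_i| / v_i and the relative average change rate
  RACR_s = |v_{i+1} - v_i| / mean(v1..v4) (segment order: plain-arterial,
  arterial-portal, portal-equilibrium);
- linear fit (2): v ~ k*t + d, ordinary least squares -> (k, d);
- quadratic fit (5): v ~ a*t^2 + b*t + c -> (a, b, c), plus the curvature
  profile QK(t) = |2a| / (1 + (2a*t + b)^2)^{3/2}: T_maxQK = argmax_t QK =
  -b/(2a) (the parabola vertex, unconstrained), and QK_max_feature = QK at
  the time point of the maximal observed series value (earliest on ties);
- exponential fit (4): v ~ alpha*e^t + beta (linear LS on basis {e^t, 1}),
  plus EK(t) = |alpha*e^t| / (1 + alpha*e^{2t})^{3/2}: T_maxEK = numeric
  argmax of EK over [t1, t4] (grid refinement to 1e-6) and EK_max_feature
  analogous to the quadratic case.

The EK formula is implemented in this printed form by default; it is not
the exact curvature of alpha*e^t + beta (which has alpha^2*e^{2t} in the
denominator) — pass ``corrected_curvature=True`` for the exact form. Under
the printed form, 1 + alpha*e^{2t} can be non-positive for alpha < 0; EK is
NaN there and those points are excluded from the argmax.

Degeneracies (zero denominators, a = 0) produce NaN or the documented
conventions, never exceptions; NaNs are imputed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .static_features import StaticFeatureVector

N_PHASES = 4
N_DYNAMIC_TYPES = 20
SEGMENTS = ("seg1", "seg2", "seg3")  # plain-arterial, arterial-portal, portal-equilibrium

DYNAMIC_TYPES: tuple[tuple[str, str], ...] = (
    ("integrated", "mean"),
    ("integrated", "variance"),
    ("integrated", "cv"),
    ("discrete", "RCR_seg1"),
    ("discrete", "RCR_seg2"),
    ("discrete", "RCR_seg3"),
    ("discrete", "RACR_seg1"),
    ("discrete", "RACR_seg2"),
    ("discrete", "RACR_seg3"),
    ("linear", "k"),
    ("linear", "d"),
    ("quadratic", "a"),
    ("quadratic", "b"),
    ("quadratic", "c"),
    ("quadratic", "T_maxQK"),
    ("quadratic", "QK_max_feature"),
    ("exponential", "alpha"),
    ("exponential", "beta"),
    ("exponential", "T_maxEK"),
    ("exponential", "EK_max_feature"),
)

DYNAMIC_TYPE_NAMES = tuple(f"{fam}__{param}" for fam, param in DYNAMIC_TYPES)

RACRMode = Literal["series-mean", "segment-midpoint"]

__all__ = [
    "N_DYNAMIC_TYPES",
    "DYNAMIC_TYPES",
    "DYNAMIC_TYPE_NAMES",
    "SEGMENTS",
    "FeatureSeries",
    "DynamicFeatureVector",
    "ek_curve",
    "dynamic_block_matrix",
    "integrated_features",
    "discrete_features",
    "fit_linear",
    "fit_quadratic",
    "fit_exponential",
    "build_dynamic_vector",
    "dynamic_matrix",
]


@dataclass
class FeatureSeries:
    """One static feature's 4-phase trajectory."""

    static_feature_name: str
    values: np.ndarray
    time_grid: tuple[float, float, float, float] = (1.0, 2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_PHASES,):
            raise ValueError("a feature series holds exactly 4 values")
        if len(self.time_grid) != N_PHASES or np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be 4 strictly increasing values")


@dataclass
class DynamicFeatureVector:
    """All 20 x 484 = 9680 dynamic feature values of one patient."""

    patient_id: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != len(self.values):
            raise ValueError("names/values mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def ek_curve(alpha: float | np.ndarray, t: np.ndarray,
             corrected: bool = False) -> np.ndarray:
    """EK(t) of a fitted exponential, NaN where the printed form is invalid."""
    a = np.asarray(alpha, dtype=np.float64)
    denom_base = 1.0 + (a ** 2 if corrected else a) * np.exp(2.0 * np.asarray(t))
    with np.errstate(invalid="ignore", divide="ignore"):
        ek = np.abs(a * np.exp(np.asarray(t))) / denom_base ** 1.5
    return np.where(denom_base > 0, ek, np.nan)


def _argmax_ek(alpha: np.ndarray, t_lo: float, t_hi: float, corrected: bool,
               n_grid: int = 601, n_refine: int = 2) -> np.ndarray:
    """Grid argmax of EK on [t_lo, t_hi], refined to < 1e-6 resolution."""
    n = alpha.shape[0]
    lo = np.full(n, t_lo)
    hi = np.full(n, t_hi)
    best = np.full(n, np.nan)
    for _ in range(1 + n_refine):
        # evaluate on per-series grids
        frac = np.linspace(0.0, 1.0, n_grid)
        grids = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
        et = np.exp(grids)
        denom_base = 1.0 + (alpha[:, None] ** 2 if corrected else alpha[:, None]) * np.exp(2.0 * grids)
        with np.errstate(invalid="ignore"):
            ek = np.abs(alpha[:, None] * et) / denom_base ** 1.5
        ek[denom_base <= 0] = np.nan
        valid = ~np.all(np.isnan(ek), axis=1)
        idx = np.zeros(n, dtype=int)
        if valid.any():
            idx[valid] = np.nanargmax(ek[valid], axis=1)
        best = np.where(valid, np.take_along_axis(grids, idx[:, None], 1)[:, 0], np.nan)
        h = (hi - lo) / (n_grid - 1)
        lo = np.clip(best - h, t_lo, t_hi)
        hi = np.clip(best + h, t_lo, t_hi)
        lo[~valid], hi[~valid] = t_lo, t_hi
    return best


def dynamic_block_matrix(
    values: np.ndarray,
    time_grid: Sequence[float] = (1.0, 2.0, 3.0, 4.0),
    racr_denominator: RACRMode = "series-mean",
    corrected_curvature: bool = False,
    chunk: int = 8192,
) -> np.ndarray:
    """Vectorised core: (n_series, 4) trajectories -> (n_series, 20) blocks.

    Column order follows :data:`DYNAMIC_TYPE_NAMES`. All scalar operations
    (:func:`integrated_features` etc.) delegate to this routine.
    """
    V = np.atleast_2d(np.asarray(values, dtype=np.float64))
    if V.shape[1] != N_PHASES:
        raise ValueError("series must have 4 phases")
    t = np.asarray(time_grid, dtype=np.float64)
    if t.shape != (N_PHASES,) or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be 4 strictly increasing values")
    n = V.shape[0]
    out = np.empty((n, N_DYNAMIC_TYPES))

    mean = V.mean(axis=1)
    var = V.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.sqrt(var) / mean
    cv[mean == 0] = np.nan
    out[:, 0], out[:, 1], out[:, 2] = mean, var, cv

    diffs = np.abs(np.diff(V, axis=1))  # (n, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        rcr = diffs / V[:, :3]
    rcr[V[:, :3] == 0] = np.nan
    if racr_denominator == "series-mean":
        denom = np.repeat(mean[:, None], 3, axis=1)
    elif racr_denominator == "segment-midpoint":
        denom = (V[:, :3] + V[:, 1:]) / 2.0
    else:
        raise ValueError(f"unknown RACR denominator mode: {racr_denominator}")
    with np.errstate(divide="ignore", invalid="ignore"):
        racr = diffs / denom
    racr[denom == 0] = np.nan
    out[:, 3:6], out[:, 6:9] = rcr, racr

    # linear and quadratic fits via precomputed pseudo-inverses
    X1 = np.column_stack([t, np.ones(N_PHASES)])
    kd = V @ np.linalg.pinv(X1).T  # (n, 2)
    out[:, 9:11] = kd

    # snap negligible leading coefficients to exact zero so the documented
    # degenerate conventions (a = 0, alpha = 0) trigger on constant series
    coeff_tol = 1e-10 * np.maximum(1.0, np.abs(V).max(axis=1))

    X2 = np.column_stack([t ** 2, t, np.ones(N_PHASES)])
    abc = V @ np.linalg.pinv(X2).T  # (n, 3): a, b, c
    abc[np.abs(abc[:, 0]) <= coeff_tol, 0] = 0.0
    a, b = abc[:, 0], abc[:, 1]
    out[:, 11:14] = abc
    with np.errstate(divide="ignore", invalid="ignore"):
        t_maxqk = -b / (2.0 * a)
    t_maxqk[a == 0] = t[0]
    out[:, 14] = t_maxqk
    t_star = t[np.argmax(V, axis=1)]  # earliest max on ties
    qk_at = np.abs(2.0 * a) / (1.0 + (2.0 * a * t_star + b) ** 2) ** 1.5
    qk_at[a == 0] = 0.0
    out[:, 15] = qk_at

    Xe = np.column_stack([np.exp(t), np.ones(N_PHASES)])
    ab = V @ np.linalg.pinv(Xe).T  # (n, 2): alpha, beta
    ab[np.abs(ab[:, 0]) <= coeff_tol, 0] = 0.0
    alpha = ab[:, 0]
    out[:, 16:18] = ab
    t_maxek = np.empty(n)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        t_maxek[sl] = _argmax_ek(alpha[sl], t[0], t[-1], corrected_curvature)
    denom_base = 1.0 + (alpha ** 2 if corrected_curvature else alpha) * np.exp(2.0 * t_star)
    with np.errstate(invalid="ignore"):
        ek_at = np.abs(alpha * np.exp(t_star)) / denom_base ** 1.5
    ek_at[denom_base <= 0] = np.nan
    out[:, 18], out[:, 19] = t_maxek, ek_at
    return out


def _block(series: FeatureSeries, **kw) -> np.ndarray:
    return dynamic_block_matrix(series.values[None, :], series.time_grid, **kw)[0]


def integrated_features(series: FeatureSeries) -> dict[str, float]:
    """Mean, population variance and coefficient of variation of the series."""
    b = _block(series)
    return {"mean": b[0], "variance": b[1], "coefficient_of_variation": b[2]}


def discrete_features(series: FeatureSeries,
                      racr_denominator: RACRMode = "series-mean") -> dict[str, float]:
    """RCR and RACR for the three consecutive phase segments."""
    b = _block(series, racr_denominator=racr_denominator)
    names = [f"RCR_{s}" for s in SEGMENTS] + [f"RACR_{s}" for s in SEGMENTS]
    return dict(zip(names, b[3:9]))


def fit_linear(series: FeatureSeries) -> tuple[float, float]:
    """OLS line v = k*t + d; returns (k_lin, d_lin)."""
    b = _block(series)
    return float(b[9]), float(b[10])


def fit_quadratic(series: FeatureSeries) -> dict[str, float]:
    """LS parabola and its curvature summaries (a, b, c, T_maxQK, QK_max_feature)."""
    blk = _block(series)
    return {
        "a": blk[11], "b": blk[12], "c": blk[13],
        "T_maxQK": blk[14], "QK_max_feature": blk[15],
    }


def fit_exponential(series: FeatureSeries,
                    corrected_curvature: bool = False) -> dict[str, float]:
    """LS fit of alpha*e^t + beta and its curvature summaries."""
    blk = _block(series, corrected_curvature=corrected_curvature)
    return {
        "alpha": blk[16], "beta": blk[17],
        "T_maxEK": blk[18], "EK_max_feature": blk[19],
    }


def build_dynamic_vector(
    static_vectors: Sequence[StaticFeatureVector],
    time_grid: Sequence[float] = (1.0, 2.0, 3.0, 4.0),
    patient_id: str = "",
    racr_denominator: RACRMode = "series-mean",
    corrected_curvature: bool = False,
) -> DynamicFeatureVector:
    """Assemble the 20 x 484 = 9680 dynamic features of one patient.

    The four static vectors must share an identical feature ordering; the
    output is static-feature-major: for each static feature, its 20-entry
    dynamic block, named ``family__param__static-name``.
    """
    if len(static_vectors) != N_PHASES:
        raise ValueError("exactly 4 phase vectors required")
    names0 = static_vectors[0].names
    for sv in static_vectors[1:]:
        if sv.names != names0:
            raise ValueError("phase vectors have mismatched feature orderings")
    V = np.stack([sv.values for sv in static_vectors], axis=1)  # (484, 4)
    blocks = dynamic_block_matrix(
        V, time_grid, racr_denominator=racr_denominator,
        corrected_curvature=corrected_curvature,
    )  # (484, 20)
    names = tuple(
        f"{dt}__{static_name}" for static_name in names0 for dt in DYNAMIC_TYPE_NAMES
    )
    return DynamicFeatureVector(patient_id=patient_id, names=names,
                                values=blocks.ravel())


def dynamic_matrix(
    phase_matrices: Sequence[pd.DataFrame],
    time_grid: Sequence[float] = (1.0, 2.0, 3.0, 4.0),
    racr_denominator: RACRMode = "series-mean",
    corrected_curvature: bool = False,
) -> pd.DataFrame:
    """Cohort-level dynamic features from 4 per-phase static feature tables.

    Each input frame is (patients x features) with identical index/columns;
    output is (patients x 20*features), static-feature-major.
    """
    if len(phase_matrices) != N_PHASES:
        raise ValueError("exactly 4 phase matrices required")
    base = phase_matrices[0]
    for m in phase_matrices[1:]:
        if not (m.index.equals(base.index) and m.columns.equals(base.columns)):
            raise ValueError("phase matrices must share index and columns")
    n_pat, n_feat = base.shape
    V = np.stack([m.to_numpy(dtype=np.float64) for m in phase_matrices], axis=2)
    blocks = dynamic_block_matrix(
        V.reshape(n_pat * n_feat, N_PHASES), time_grid,
        racr_denominator=racr_denominator, corrected_curvature=corrected_curvature,
    ).reshape(n_pat, n_feat * N_DYNAMIC_TYPES)
    cols = [f"{dt}__{feat}" for feat in base.columns for dt in DYNAMIC_TYPE_NAMES]
    return pd.DataFrame(blocks, index=base.index, columns=cols)
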