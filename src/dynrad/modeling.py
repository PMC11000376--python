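"""Signature construction and evaluation.

The modeling chain follows the radiomics-standard recipe: reproducibility
filtering by intraclass correlation (ICC > 0.8 for both intra- and
inter-observer repeats), training-median imputation, z-score
standardisation, univariate F-test screening (p < 0.05), LASSO-logistic
feature selection with the penalty chosen by repeated stratified 5x5-fold
cross-validation maximising mean AUC, and a final unpenalised logistic fit.
The SR (static), DR (dynamic) and DSR (combined) signatures share this
machinery and differ only in their input columns.

Every data-derived constant (medians, scaling, selected features, operating
threshold) comes from the training cohort alone; validation data are only
ever transformed with frozen parameters.

AUC inference (confidence intervals and paired signature comparison) uses
the DeLong covariance of the ROC-area U-statistic, implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold

__all__ = [
    "icc_2way_random_single",
    "icc_filter",
    "standardize",
    "f_test_screen",
    "lasso_select",
    "SignatureModel",
    "build_signature",
    "EvaluationReport",
    "evaluate",
    "rank_auc",
    "delong_variance",
    "delong_ci",
    "delong_test",
    "compare_auc",
]


# ---------------------------------------------------------------------------
# reproducibility filtering


def icc_2way_random_single(measurements: np.ndarray) -> np.ndarray:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` has shape (subjects, raters) or (subjects, raters,
    features); the ICC is computed per feature from the two-way ANOVA mean
    squares. Zero between-subject variance makes the ICC undefined (NaN).
    """
    Y = np.asarray(measurements, dtype=np.float64)
    if Y.ndim == 2:
        Y = Y[:, :, None]
    n, k, _ = Y.shape
    grand = Y.mean(axis=(0, 1))
    subj = Y.mean(axis=1)
    rater = Y.mean(axis=0)
    ssb = k * ((subj - grand) ** 2).sum(axis=0)
    ssc = n * ((rater - grand) ** 2).sum(axis=0)
    sst = ((Y - grand) ** 2).sum(axis=(0, 1))
    sse = np.maximum(sst - ssb - ssc, 0.0)
    msr = ssb / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    icc[denom == 0] = np.nan
    return icc


def icc_filter(
    features_r1a: pd.DataFrame,
    features_r1b: pd.DataFrame,
    features_r2: pd.DataFrame,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Per-feature reproducibility table from the two-reader repeat design.

    ``features_r1a`` / ``features_r1b`` are reader 1's two segmentations,
    ``features_r2`` reader 2's; intra-observer ICC compares r1a vs r1b,
    inter-observer r1a vs r2. A feature passes iff both ICCs > threshold
    (NaN ICCs fail). Returns a frame indexed by feature with columns
    intra_observer_icc, inter_observer_icc, passed.
    """
    if not (features_r1a.columns.equals(features_r1b.columns)
            and features_r1a.columns.equals(features_r2.columns)):
        raise ValueError("feature matrices must share columns")
    if not (len(features_r1a) == len(features_r1b) == len(features_r2)):
        raise ValueError("feature matrices must share patients")
    a = features_r1a.to_numpy(dtype=np.float64)
    intra = icc_2way_random_single(np.stack([a, features_r1b.to_numpy(np.float64)], axis=1))
    inter = icc_2way_random_single(np.stack([a, features_r2.to_numpy(np.float64)], axis=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        passed = (intra > threshold) & (inter > threshold)
    passed = np.where(np.isnan(intra) | np.isnan(inter), False, passed)
    return pd.DataFrame(
        {"intra_observer_icc": intra, "inter_observer_icc": inter, "passed": passed},
        index=features_r1a.columns,
    )


# ---------------------------------------------------------------------------
# screening and selection


def standardize(train: pd.DataFrame, apply_to: pd.DataFrame) -> pd.DataFrame:
    """Z-score ``apply_to`` using means/sds learned from ``train`` only.

    Columns constant in training are dropped from the output (with a
    warning) since they carry no information and have sd = 0.
    """
    means = train.mean()
    sds = train.std(ddof=0)
    keep = sds > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant training columns")
    cols = train.columns[keep]
    return (apply_to[cols] - means[cols]) / sds[cols]


def f_test_screen(X: pd.DataFrame, y: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Univariate one-way ANOVA screen: keep features with p < alpha.

    NaNs are median-imputed (column medians of ``X``) before testing. If no
    feature clears alpha, the single smallest-p feature is kept so the
    downstream pipeline always has input (logged via warning).
    """
    y = np.asarray(y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    Xi = X.fillna(X.median()).fillna(0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, pvals = f_classif(Xi.to_numpy(dtype=np.float64), y)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    keep = pvals < alpha
    if not keep.any():
        warnings.warn("F-test kept no feature; falling back to the smallest p-value")
        keep[np.argmin(pvals)] = True
    return [c for c, k in zip(X.columns, keep) if k]


def _cv_auc(X: np.ndarray, y: np.ndarray, C: float, folds: int, repeats: int,
            seed: int) -> float:
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                   random_state=seed)
    aucs = []
    for tr, te in rskf.split(X, y):
        if len(np.unique(y[te])) < 2:
            continue
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 max_iter=2000, random_state=seed)
        clf.fit(X[tr], y[tr])
        aucs.append(rank_auc(y[te], clf.decision_function(X[te])))
    return float(np.mean(aucs)) if aucs else 0.5


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    cv_folds: int = 5,
    cv_repeats: int = 5,
    seed: int = 0,
    c_grid: Sequence[float] | None = None,
) -> list[str]:
    """L1-logistic feature selection on standardised inputs.

    The inverse penalty C is chosen on a log grid by repeated stratified
    cross-validation maximising mean AUC (ties favour the stronger
    penalty); features with nonzero coefficients in the full-data refit at
    that C are returned. An empty selection falls back to the weakest
    penalty on the grid that yields at least one feature.
    """
    y = np.asarray(y)
    Xa = X.to_numpy(dtype=np.float64)
    grid = np.asarray(c_grid if c_grid is not None else np.logspace(-2, 1.5, 8))
    grid = np.sort(grid)
    scores = [_cv_auc(Xa, y, C, cv_folds, cv_repeats, seed) for C in grid]
    best_c = grid[int(np.argmax(scores))]  # argmax takes the smallest C on ties

    def _nonzero(C: float) -> list[str]:
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 max_iter=2000, random_state=seed)
        clf.fit(Xa, y)
        nz = np.abs(clf.coef_[0]) > 0
        return [c for c, k in zip(X.columns, nz) if k]

    selected = _nonzero(best_c)
    if not selected:
        for C in grid[grid > best_c]:
            selected = _nonzero(C)
            if selected:
                warnings.warn(f"empty LASSO selection at C={best_c:g}; using C={C:g}")
                break
    return selected


# ---------------------------------------------------------------------------
# signatures


@dataclass
class SignatureModel:
    """A fitted radiomics signature: selection + scaling + logistic score.

    All parameters are training-derived. ``medians``/``means``/``sds`` are
    aligned with ``feature_names`` and define the frozen transform applied
    to any new cohort before the linear score.
    """

    signature_type: str
    feature_names: list[str]
    medians: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    coefficients: np.ndarray
    intercept: float
    threshold: float
    n_input_features: int = 0
    n_after_screen: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.feature_names)
        for arr_name in ("medians", "means", "sds", "coefficients"):
            arr = np.asarray(getattr(self, arr_name), dtype=np.float64)
            if arr.shape != (m,):
                raise ValueError(f"{arr_name} must align with selected features")
            setattr(self, arr_name, arr)
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("decision threshold must be in (0, 1)")

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Frozen impute + z-score of the selected columns."""
        Z = X[self.feature_names].to_numpy(dtype=np.float64)
        nan = np.isnan(Z)
        if nan.any():
            Z = np.where(nan, np.broadcast_to(self.medians, Z.shape), Z)
        return (Z - self.means) / self.sds

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self.transform(X) @ self.coefficients + self.intercept

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signature_type": self.signature_type,
            "feature_names": self.feature_names,
            "medians": self.medians.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
            "n_input_features": self.n_input_features,
            "n_after_screen": self.n_after_screen,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        return cls(**json.loads(Path(path).read_text()))


def _youden_threshold(y: np.ndarray, proba: np.ndarray) -> float:
    fpr, tpr, thr = roc_curve(y, proba)
    j = tpr - fpr
    order = np.argsort(-j, kind="stable")
    for idx in order:
        t = thr[idx]
        if 0.0 < t < 1.0:
            return float(t)
    return 0.5


def build_signature(
    X: pd.DataFrame,
    y: np.ndarray,
    signature_type: str = "SR",
    alpha: float = 0.05,
    cv_folds: int = 5,
    cv_repeats: int = 5,
    seed: int = 0,
    c_grid: Sequence[float] | None = None,
) -> SignatureModel:
    """Fit one signature on a training cohort.

    Pipeline: training-median imputation -> z-score -> F-test screen ->
    LASSO selection (penalty by repeated 5x5 CV) -> unpenalised logistic on
    the survivors -> Youden-optimal probability threshold on the training
    ROC. For SR pass the 4x484 static table, for DR the 9680-column dynamic
    table, for DSR the union of the SR- and DR-selected columns.
    """
    y = np.asarray(y).astype(int)
    medians_all = X.median()
    Xi = X.fillna(medians_all).fillna(0.0)
    sds_all = Xi.std(ddof=0)
    Xi = Xi.loc[:, sds_all > 0]
    Z = (Xi - Xi.mean()) / Xi.std(ddof=0)

    screened = f_test_screen(Z, y, alpha=alpha)
    selected = lasso_select(Z[screened], y, cv_folds=cv_folds,
                            cv_repeats=cv_repeats, seed=seed, c_grid=c_grid)
    if not selected:  # pathological: fall back to the screened set
        selected = screened[: min(5, len(screened))]

    clf = LogisticRegression(C=np.inf, max_iter=5000)
    clf.fit(Z[selected].to_numpy(), y)
    proba = clf.predict_proba(Z[selected].to_numpy())[:, 1]
    model = SignatureModel(
        signature_type=signature_type,
        feature_names=list(selected),
        medians=medians_all[selected].to_numpy(dtype=np.float64),
        means=Xi[selected].mean().to_numpy(),
        sds=Xi[selected].std(ddof=0).to_numpy(),
        coefficients=clf.coef_[0],
        intercept=float(clf.intercept_[0]),
        threshold=_youden_threshold(y, proba),
        n_input_features=X.shape[1],
        n_after_screen=len(screened),
        provenance={"alpha": alpha, "cv_folds": cv_folds,
                    "cv_repeats": cv_repeats, "seed": seed},
    )
    return model


# ---------------------------------------------------------------------------
# evaluation: rank AUC, DeLong variance/CI/test


def rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation (ties counted half)."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=np.float64)
    pos = y == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC undefined for single-class labels")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - m * (m + 1) / 2) / (m * n))


def delong_variance(y: np.ndarray, score_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong AUCs and covariance matrix for k paired score vectors.

    ``score_matrix`` has shape (k, n_subjects). Returns (aucs, covariance)
    where covariance is (k, k).
    """
    y = np.asarray(y)
    S = np.atleast_2d(np.asarray(score_matrix, dtype=np.float64))
    pos, neg = S[:, y == 1], S[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("AUC undefined for single-class labels")
    k = S.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = stats.rankdata(pos[r])
        ty = stats.rankdata(neg[r])
        tz = stats.rankdata(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    sx = np.atleast_2d(np.cov(v01)) if m > 1 else np.zeros((k, k))
    sy = np.atleast_2d(np.cov(v10)) if n > 1 else np.zeros((k, k))
    return aucs, sx / m + sy / n


def delong_ci(y: np.ndarray, scores: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """(auc, lo, hi): normal-approximation CI with the DeLong variance."""
    aucs, cov = delong_variance(y, scores[None, :])
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = stats.norm.ppf(0.5 + level / 2)
    return float(aucs[0]), max(0.0, float(aucs[0] - z * se)), min(1.0, float(aucs[0] + z * se))


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired DeLong test; returns (z, p).

    Degenerate variance of the AUC difference yields p = 1 (no evidence of
    a difference can be quantified).
    """
    aucs, cov = delong_variance(y, np.vstack([scores_a, scores_b]))
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return 0.0, 1.0
    z = float((aucs[0] - aucs[1]) / np.sqrt(var))
    return z, float(2 * stats.norm.sf(abs(z)))


def compare_auc(model_a_scores: np.ndarray, model_b_scores: np.ndarray,
                y: np.ndarray) -> float:
    """Two-sided DeLong p-value for the paired AUC difference."""
    return delong_test(model_a_scores, model_b_scores, y)[1]


@dataclass
class EvaluationReport:
    """Discrimination summary of one signature on one cohort."""

    auc: float
    auc_ci: tuple[float, float]
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    roc: pd.DataFrame
    pr: pd.DataFrame
    n: int
    prevalence: float

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "n": self.n,
            "prevalence": self.prevalence,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def evaluate(model: SignatureModel, X: pd.DataFrame, y: np.ndarray) -> EvaluationReport:
    """Apply a fitted signature to a cohort and report its discrimination.

    AUC uses the rank formulation with a DeLong 95% CI; accuracy,
    sensitivity and specificity are taken at the model's (training-derived)
    probability threshold; full ROC and precision-recall point sets are
    included.
    """
    y = np.asarray(y).astype(int)
    proba = model.predict_proba(X)
    auc, lo, hi = delong_ci(y, proba)
    pred = (proba >= model.threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fpr, tpr, roc_thr = roc_curve(y, proba)
    prec, rec, _ = precision_recall_curve(y, proba)
    return EvaluationReport(
        auc=auc,
        auc_ci=(lo, hi),
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        threshold=model.threshold,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr}),
        pr=pd.DataFrame({"precision": prec, "recall": rec}),
        n=len(y),
        prevalence=float(y.mean()),
    )
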