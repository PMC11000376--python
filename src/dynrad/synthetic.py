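"""Self-contained synthetic 4-phase cohorts for exercising the pipeline.

Two tiers of generators:

* :func:`generate_cohort` builds voxel phantoms — an ellipsoidal lesion in a
  smooth background whose in-lesion mean intensity follows a class-specific
  4-point enhancement trajectory (wash-in to an arterial peak, then
  washout), with a correlated random texture field inside the lesion and
  per-phase additive noise. These emulate the *structure* of multi-phase
  liver MR (4 phases, per-phase tumor masks, class-dependent kinetics and
  heterogeneity), not its anatomy or MR physics.

* :func:`generate_feature_series` skips images and directly emits 4
  per-phase static-feature matrices with controlled class structure:
  ``"none"`` is an exchangeable null; ``"marginal"`` plants a per-phase
  mean shift (visible to static models); ``"temporal-only"`` plants signal
  exclusively in the *ordering* of values across phases while matching the
  per-phase marginal distribution of the two classes exactly, so any
  linear static classifier has population AUC 0.5 but absolute inter-phase
  changes separate the classes.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import PHASE_NAMES, PhaseStack, save_stack

__all__ = [
    "SyntheticCohortConfig",
    "generate_cohort",
    "generate_reader_variants",
    "generate_feature_series",
    "write_cohort",
]

# temporal-only trajectory shapes: same per-phase amplitude multiset, so the
# +/- sign mixture gives both classes identical per-phase marginals; the
# absolute inter-phase changes differ (monotone: (2,1,1) vs zigzag: (4,1,2)
# in half-amplitude units), which only dynamic features can exploit.
_MONOTONE_PROFILE = np.array([-1.5, -0.5, 0.5, 1.5])
_ZIGZAG_PROFILE = np.array([-1.5, 0.5, -0.5, 1.5])


@dataclass
class SyntheticCohortConfig:
    """Phantom cohort parameters.

    ``kinetics_by_class`` maps the binary label to the lesion's mean
    intensity at (plain, arterial, portal venous, equilibrium);
    ``texture_heterogeneity_by_class`` maps it to (correlation length in
    voxels, amplitude) of the random field added inside the lesion.
    """

    n_patients: int = 20
    prevalence: float = 0.34
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    lesion_radius_range: tuple[float, float] = (6.0, 10.0)
    kinetics_by_class: dict = field(default_factory=lambda: {
        0: (100.0, 160.0, 150.0, 130.0),
        1: (100.0, 185.0, 140.0, 112.0),
    })
    texture_heterogeneity_by_class: dict = field(default_factory=lambda: {
        0: (1.5, 8.0),
        1: (3.0, 14.0),
    })
    background_level: float = 60.0
    noise_sigma: float = 5.0
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    time_grid: tuple[float, float, float, float] = (1.0, 2.0, 3.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        n_pos = round(self.n_patients * self.prevalence)
        if n_pos < 2 or self.n_patients - n_pos < 2:
            raise ValueError("each class needs at least 2 patients")
        if self.lesion_radius_range[0] <= 0:
            raise ValueError("lesion radius must be positive")
        if 2 * self.lesion_radius_range[1] >= min(self.volume_shape):
            raise ValueError("lesion larger than volume")


def _labels(n: int, prevalence: float, rng: np.random.Generator) -> np.ndarray:
    n_pos = round(n * prevalence)
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    return labels


def _smooth_field(shape, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_len)
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape).astype(np.float64)
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return d2 <= 1.0


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[PhaseStack], np.ndarray, pd.DataFrame]:
    """Build the phantom cohort; returns (stacks, labels, manifest)."""
    rng = np.random.default_rng(config.seed)
    labels = _labels(config.n_patients, config.prevalence, rng)
    shape = config.volume_shape
    stacks: list[PhaseStack] = []
    rows = []
    for p in range(config.n_patients):
        cls = int(labels[p])
        traj = np.asarray(config.kinetics_by_class[cls], dtype=np.float64)
        corr_len, tex_amp = config.texture_heterogeneity_by_class[cls]
        center = np.array(shape) / 2.0 + rng.uniform(-2, 2, size=3)
        semi_axes = rng.uniform(*config.lesion_radius_range, size=3)
        lesion = _ellipsoid(shape, center, semi_axes)
        if not lesion.any():
            raise ValueError("lesion degenerated to empty support")
        background = config.background_level + 5.0 * _smooth_field(shape, 4.0, rng)
        texture = tex_amp * _smooth_field(shape, corr_len, rng)
        volumes, masks = [], []
        for ph in range(4):
            vol = background.copy()
            vol[lesion] = traj[ph] + texture[lesion]
            if config.noise_model == "rician":
                n1 = rng.normal(0, config.noise_sigma, shape)
                n2 = rng.normal(0, config.noise_sigma, shape)
                vol = np.sqrt((vol + n1) ** 2 + n2 ** 2)
            else:
                vol = vol + rng.normal(0, config.noise_sigma, shape)
            volumes.append(vol)
            masks.append(lesion.astype(np.uint8))
        stacks.append(PhaseStack(volumes, masks, spacing=(1.0, 1.0, 1.0),
                                 time_grid=config.time_grid,
                                 meta={"patient_id": f"P{p:03d}", "label": cls}))
        rows.append({"patient_id": f"P{p:03d}", "label": cls})
    return stacks, labels, pd.DataFrame(rows)


def generate_reader_variants(
    stack: PhaseStack, jitter_mm: float, seed: int = 0
) -> tuple[PhaseStack, PhaseStack]:
    """Two re-segmentations of a stack's masks (repeat reader + second reader).

    Each variant perturbs every phase mask by adding a smooth random field
    (unit sd, scaled by ``jitter_mm``) to the mask's signed Euclidean
    distance map and re-thresholding at zero; ``jitter_mm = 0`` reproduces
    the masks exactly. Volumes are shared untouched.
    """
    if jitter_mm < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)

    def _variant() -> PhaseStack:
        masks = []
        for msk in stack.masks:
            if jitter_mm == 0:
                masks.append(msk.copy())
                continue
            inside = ndimage.distance_transform_edt(msk, sampling=stack.spacing)
            outside = ndimage.distance_transform_edt(1 - msk, sampling=stack.spacing)
            signed = inside - outside
            new = (signed + jitter_mm * _smooth_field(msk.shape, 2.0, rng)) > 0
            if not new.any():
                raise ValueError("jitter collapsed a mask to empty")
            masks.append(new.astype(np.uint8))
        return PhaseStack([v.copy() for v in stack.volumes], masks,
                          spacing=stack.spacing, time_grid=stack.time_grid,
                          meta=dict(stack.meta))

    return _variant(), _variant()


def generate_feature_series(
    n_features: int = 200,
    class_effect: Literal["temporal-only", "marginal", "none"] = "none",
    n_patients: int = 200,
    seed: int = 0,
    prevalence: float = 0.4,
    baseline: float = 10.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.6,
    informative_frac: float = 0.15,
    marginal_shift: float = 0.8,
) -> tuple[list[pd.DataFrame], np.ndarray]:
    """Directly simulate 4 per-phase static-feature matrices plus labels.

    Informative features (the first ``round(informative_frac*n_features)``)
    carry the class signal; the rest are exchangeable noise. Under
    ``"temporal-only"`` each informative feature's trajectory is a random
    +/- sign times a monotone profile (class 0) or a zigzag permutation of
    the same per-phase amplitudes (class 1), centred on ``baseline``: the
    per-phase marginals of the two classes are identical by construction.
    """
    rng = np.random.default_rng(seed)
    labels = _labels(n_patients, prevalence, rng)
    n_inf = round(informative_frac * n_features) if class_effect != "none" else 0
    X = baseline + rng.normal(0.0, noise_sd, size=(n_patients, n_features, 4))
    if class_effect == "temporal-only":
        signs = rng.choice([-1.0, 1.0], size=(n_patients, n_inf, 1))
        profiles = np.where(labels[:, None, None] == 0,
                            _MONOTONE_PROFILE[None, None, :],
                            _ZIGZAG_PROFILE[None, None, :])
        X[:, :n_inf, :] += amplitude * signs * profiles
    elif class_effect == "marginal":
        # arterial-phase mean shift for the positive class
        X[labels == 1, :n_inf, 1] += marginal_shift
    elif class_effect != "none":
        raise ValueError(f"unknown class_effect: {class_effect}")
    cols = [f"F{i:04d}" for i in range(n_features)]
    idx = [f"P{i:04d}" for i in range(n_patients)]
    mats = [pd.DataFrame(X[:, :, ph], index=idx, columns=cols) for ph in range(4)]
    return mats, labels


def write_cohort(
    stacks: list[PhaseStack], labels: np.ndarray, out_dir: str | Path
) -> pd.DataFrame:
    """Write a phantom cohort as NIfTI files + a manifest CSV.

    The manifest has the real-data layout: patient_id, label, and one
    volume/mask path column per phase.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (stack, label) in enumerate(zip(stacks, labels)):
        pid = stack.meta.get("patient_id", f"P{i:03d}")
        sidecar = save_stack(stack, out_dir, pid)
        row: dict = {"patient_id": pid, "label": int(label)}
        for name in PHASE_NAMES:
            row[f"{name}_image"] = sidecar["paths"][f"{name}_img"]
            row[f"{name}_mask"] = sidecar["paths"][f"{name}_msk"]
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
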