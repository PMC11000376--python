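"""Loading, spatial harmonisation, intensity normalisation and gray-level
quantisation of multi-phase contrast-enhanced MR volumes.

A study "case" is a :class:`PhaseStack`: four co-acquired 3D volumes
(plain/"mask", arterial, portal venous, equilibrium phases), one binary tumor
mask per phase, the voxel spacing, and a time grid giving each phase a time
coordinate (phase indices 1..4 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import SimpleITK as sitk

PHASE_NAMES = ("plain", "arterial", "portal", "equilibrium")
N_PHASES = 4

__all__ = [
    "PHASE_NAMES",
    "N_PHASES",
    "PhaseStack",
    "QuantizedROI",
    "load_phase_stack",
    "resample_isotropic",
    "znormalize",
    "quantize_gray_levels",
]


@dataclass
class PhaseStack:
    """Four registered-grid phase volumes with per-phase binary ROI masks.

    volumes / masks are ordered (plain, arterial, portal venous, equilibrium).
    ``spacing`` is the voxel edge length in mm per axis; ``time_grid`` the
    strictly increasing time coordinate of each phase.
    """

    volumes: list[np.ndarray]
    masks: list[np.ndarray]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    time_grid: tuple[float, float, float, float] = (1.0, 2.0, 3.0, 4.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.volumes) != N_PHASES or len(self.masks) != N_PHASES:
            raise ValueError(f"exactly {N_PHASES} phases required")
        if len(self.time_grid) != N_PHASES or np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be 4 strictly increasing values")
        for i, (vol, msk) in enumerate(zip(self.volumes, self.masks)):
            vol = np.asarray(vol, dtype=np.float64)
            msk = np.asarray(msk)
            if vol.ndim != 3:
                raise ValueError(f"phase {i}: volume must be 3D")
            if vol.shape != msk.shape:
                raise ValueError(f"phase {i}: mask grid does not match volume grid")
            uniq = np.unique(msk)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"phase {i}: non-binary mask (values {uniq})")
            if msk.sum() < 1:
                raise ValueError(f"phase {i}: empty mask")
            self.volumes[i] = vol
            self.masks[i] = msk.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.time_grid = tuple(float(t) for t in self.time_grid)


@dataclass
class QuantizedROI:
    """Integer gray levels (1..n_levels) of the in-mask voxels, with geometry.

    ``geometry`` keeps each ROI voxel's coordinates on the resampled grid so
    that spatial texture matrices can be built; ``shape`` is the grid shape.
    """

    values: np.ndarray
    n_levels: int
    geometry: np.ndarray  # (n_voxels, 3) int coordinates
    shape: tuple[int, int, int]

    def to_volume(self) -> np.ndarray:
        """ROI re-embedded in its grid; 0 marks out-of-ROI voxels."""
        out = np.zeros(self.shape, dtype=np.int32)
        out[tuple(self.geometry.T)] = self.values
        return out


def _read_image(path: str | Path) -> sitk.Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    return sitk.ReadImage(str(path))


def load_phase_stack(
    volume_paths: Sequence[str | Path],
    mask_paths: Sequence[str | Path],
    time_grid: Sequence[float] = (1.0, 2.0, 3.0, 4.0),
) -> PhaseStack:
    """Read 4 volume/mask NIfTI or NRRD pairs into a validated PhaseStack."""
    if len(volume_paths) != N_PHASES or len(mask_paths) != N_PHASES:
        raise ValueError(f"exactly {N_PHASES} phases required")
    volumes, masks, spacing = [], [], None
    for vp, mp in zip(volume_paths, mask_paths):
        vimg, mimg = _read_image(vp), _read_image(mp)
        if vimg.GetSize() != mimg.GetSize():
            raise ValueError(f"mask grid does not match volume grid: {mp}")
        sp = vimg.GetSpacing()[::-1]  # sitk is (x,y,z); arrays are (z,y,x)
        if spacing is None:
            spacing = sp
        volumes.append(sitk.GetArrayFromImage(vimg).astype(np.float64))
        masks.append(sitk.GetArrayFromImage(mimg))
    return PhaseStack(volumes, masks, spacing=spacing, time_grid=tuple(time_grid))


def _resample(img: sitk.Image, target_spacing, interpolator) -> sitk.Image:
    in_spacing = np.asarray(img.GetSpacing(), dtype=float)
    in_size = np.asarray(img.GetSize(), dtype=int)
    out_spacing = np.asarray(target_spacing, dtype=float)
    out_size = np.maximum(1, np.round(in_size * in_spacing / out_spacing)).astype(int)
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(out_spacing))
    res.SetSize([int(s) for s in out_size])
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(interpolator)
    return res.Execute(img)


def resample_isotropic(
    stack: PhaseStack,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> PhaseStack:
    """Resample every phase to a common isotropic grid.

    Volumes use trilinear interpolation, masks nearest-neighbour so they stay
    binary. ``target_spacing`` is in mm, array-axis order (z, y, x).
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    sp_xyz = tuple(float(s) for s in stack.spacing[::-1])
    tgt_xyz = tuple(float(s) for s in target_spacing[::-1])
    volumes, masks = [], []
    for vol, msk in zip(stack.volumes, stack.masks):
        vimg = sitk.GetImageFromArray(vol)
        vimg.SetSpacing(sp_xyz)
        mimg = sitk.GetImageFromArray(msk.astype(np.uint8))
        mimg.SetSpacing(sp_xyz)
        volumes.append(sitk.GetArrayFromImage(_resample(vimg, tgt_xyz, sitk.sitkLinear)))
        masks.append(sitk.GetArrayFromImage(_resample(mimg, tgt_xyz, sitk.sitkNearestNeighbor)))
    return PhaseStack(
        volumes, masks, spacing=tuple(target_spacing), time_grid=stack.time_grid,
        meta=dict(stack.meta),
    )


def znormalize(
    volume: np.ndarray,
    region: Literal["whole-volume", "mask-only"] = "whole-volume",
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Z-score the volume: x' = (x - mu) / sigma.

    mu and sigma are taken over the whole volume by default, or over the mask
    when ``region="mask-only"``. A constant region (sigma = 0) is a degenerate
    input and raises.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if region == "mask-only":
        if mask is None:
            raise ValueError("mask-only normalization requires a mask")
        sel = volume[np.asarray(mask).astype(bool)]
    else:
        sel = volume.ravel()
    mu, sigma = float(np.mean(sel)), float(np.std(sel))
    if sigma == 0:
        raise ValueError("constant region: sigma = 0, cannot z-normalize")
    return (volume - mu) / sigma


def quantize_gray_levels(
    volume: np.ndarray, mask: np.ndarray, n_levels: int = 64
) -> QuantizedROI:
    """Equal-width binning of in-mask intensities into levels 1..n_levels.

    Bin edges span the ROI min..max, so the ROI minimum maps to level 1 and
    the maximum to level ``n_levels`` (the 1-64 gray-level convention).
    A constant ROI maps every voxel to level 1.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 1:
        raise ValueError("empty mask")
    volume = np.asarray(volume, dtype=np.float64)
    vals = volume[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        levels = np.ones(vals.shape, dtype=np.int32)
    else:
        levels = np.floor((vals - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
        np.clip(levels, 1, n_levels, out=levels)
    geometry = np.argwhere(mask)
    return QuantizedROI(values=levels, n_levels=int(n_levels),
                        geometry=geometry, shape=volume.shape)


def save_stack(stack: PhaseStack, out_dir: str | Path, case_id: str) -> dict:
    """Cache a stack as NIfTI files plus a JSON sidecar; returns the sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for name, vol, msk in zip(PHASE_NAMES, stack.volumes, stack.masks):
        for kind, arr in (("img", vol), ("msk", msk)):
            img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
            img.SetSpacing(tuple(stack.spacing[::-1]))
            p = out_dir / f"{case_id}_{name}_{kind}.nii.gz"
            sitk.WriteImage(img, str(p))
            paths[f"{name}_{kind}"] = str(p)
    sidecar = {
        "case_id": case_id,
        "spacing_mm": list(stack.spacing),
        "time_grid": list(stack.time_grid),
        "paths": paths,
        "meta": stack.meta,
    }
    with open(out_dir / f"{case_id}_stack.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar
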