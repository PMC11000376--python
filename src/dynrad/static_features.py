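"""The 484-feature static radiomics vector for one ROI in one phase.

Composition: 7 intensity features on the (normalised) ROI intensities,
53 texture features on the 64-level quantised ROI, and the same 53 texture
features on each of the 8 sub-bands of a single-level 3D wavelet transform
(8 x 53 = 424 wavelet features) -- 484 in total.

Sub-bands are named by the per-axis filter sequence over (x, y, z): e.g.
``HLH`` is high-pass along x, low-pass along y, high-pass along z. Arrays
are indexed (z, y, x), so the name is read off the transform keys reversed.
The default transform is the stationary (undecimated) one so every sub-band
is voxel-aligned with the ROI mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt
from scipy import stats

from .preprocess import QuantizedROI, quantize_gray_levels
from .texture import (
    TEXTURE_FAMILY,
    TEXTURE_FEATURE_NAMES,
    texture_features_from_labels,
)

WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

INTENSITY_FEATURES = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Intensity energy",
    "Intensity entropy",
    "Range",
)

N_INTENSITY = 7
N_TEXTURE = 53
N_WAVELET = 8 * N_TEXTURE
N_STATIC = N_INTENSITY + N_TEXTURE + N_WAVELET  # 484

__all__ = [
    "WAVELET_BANDS",
    "INTENSITY_FEATURES",
    "N_INTENSITY",
    "N_TEXTURE",
    "N_WAVELET",
    "N_STATIC",
    "FeatureRoster",
    "StaticFeatureVector",
    "default_roster",
    "intensity_features",
    "texture_features",
    "wavelet_decompose",
    "extract_static_vector",
    "static_feature_names",
]


@dataclass(frozen=True)
class FeatureRoster:
    """Ordered definition of the intensity + texture feature banks.

    Each entry is (name, family, formula_id); families are first-order,
    GLCM, GLRLM, GLSZM and NGTDM.
    """

    entries: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        fams = [f for _, f, _ in self.entries]
        if fams.count("first-order") != N_INTENSITY or len(self.entries) != N_INTENSITY + N_TEXTURE:
            raise ValueError("roster must hold 7 first-order + 53 texture features")
        names = [n for n, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("roster names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _, _ in self.entries)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"name": n, "family": f, "formula_id": fid} for n, f, fid in self.entries
        ]
        Path(path).write_text(json.dumps(payload, indent=2))


def _formula_id(name: str) -> str:
    return name.lower().replace(" ", "_").replace("(", "").replace(")", "").replace("-", "_")


def default_roster() -> FeatureRoster:
    entries = [(n, "first-order", _formula_id(n)) for n in INTENSITY_FEATURES]
    entries += [
        (n, fam, _formula_id(n)) for n, fam in zip(TEXTURE_FEATURE_NAMES, TEXTURE_FAMILY)
    ]
    return FeatureRoster(tuple(entries))


@dataclass
class StaticFeatureVector:
    """The 484 named static feature values of one ROI in one phase."""

    phase_id: str
    names: tuple[str, ...]
    values: np.ndarray
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (len(self.names) == len(self.values) == len(self.categories) == N_STATIC):
            raise ValueError(f"static vector must have exactly {N_STATIC} entries")
        counts = {c: self.categories.count(c) for c in ("intensity", "texture", "wavelet")}
        if counts != {"intensity": N_INTENSITY, "texture": N_TEXTURE, "wavelet": N_WAVELET}:
            raise ValueError(f"category counts must be 7/53/424, got {counts}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def intensity_features(roi_values: np.ndarray, n_bins: int = 64) -> dict[str, float]:
    """First-order statistics of the ROI intensity sample.

    Variance is the population variance; skewness and kurtosis are the
    standardised third and fourth central moments (kurtosis is not
    excess-corrected) and fall back to 0 on a zero-variance ROI. Entropy is
    computed on an ``n_bins`` equal-width histogram of the ROI values.
    """
    x = np.asarray(roi_values, dtype=np.float64).ravel()
    if x.size < 1:
        raise ValueError("empty ROI")
    mu = float(x.mean())
    var = float(x.var())
    if var > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, bias=True, fisher=False))
    else:
        skew = kurt = 0.0
    hist, _ = np.histogram(x, bins=n_bins)
    p = hist[hist > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "Mean": mu,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Intensity energy": float((x ** 2).sum()),
        "Intensity entropy": entropy,
        "Range": float(x.max() - x.min()),
    }


def texture_features(roi: QuantizedROI) -> dict[str, float]:
    """The 53 texture features of a quantised ROI (matrices built in-ROI)."""
    return texture_features_from_labels(roi.to_volume(), roi.n_levels)


def wavelet_decompose(
    volume: np.ndarray, wavelet: str = "coif1", stationary: bool = True
) -> dict[str, np.ndarray]:
    """Single-level separable 3D wavelet transform into 8 named sub-bands.

    With ``stationary=True`` (default) the undecimated transform is used and
    every sub-band has the input shape, so ROI masks apply voxel-for-voxel.
    With ``stationary=False`` a decimated transform with periodic boundary
    is returned (orthogonal wavelets then conserve energy across sub-bands).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D")
    wl = pywt.Wavelet(wavelet)
    if min(volume.shape) < wl.dec_len:
        raise ValueError(
            f"volume of shape {volume.shape} too small for wavelet '{wavelet}' "
            f"(filter length {wl.dec_len})"
        )
    if stationary:
        pad = [(0, s % 2) for s in volume.shape]
        padded = np.pad(volume, pad, mode="symmetric")
        coeffs = pywt.swtn(padded, wl, level=1)[0]
        crop = tuple(slice(0, s) for s in volume.shape)
        raw = {k: v[crop] for k, v in coeffs.items()}
    else:
        raw = pywt.dwtn(volume, wl, mode="periodization")
    out: dict[str, np.ndarray] = {}
    for key, band in raw.items():
        # key letters follow array axes (z, y, x); names read over (x, y, z)
        name = "".join("L" if c == "a" else "H" for c in key[::-1])
        out[name] = band
    return {b: out[b] for b in WAVELET_BANDS}


def static_feature_names(roster: FeatureRoster | None = None) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Deterministic (names, categories) ordering of the 484-entry vector."""
    roster = roster or default_roster()
    tex_names = roster.names[N_INTENSITY:]
    names = list(roster.names[:N_INTENSITY]) + list(tex_names)
    cats = ["intensity"] * N_INTENSITY + ["texture"] * N_TEXTURE
    for band in WAVELET_BANDS:
        names += [f"{n}_wavelet.{band}" for n in tex_names]
        cats += ["wavelet"] * N_TEXTURE
    return tuple(names), tuple(cats)


def extract_static_vector(
    phase_volume: np.ndarray,
    mask: np.ndarray,
    phase_id: str = "",
    n_levels: int = 64,
    wavelet: str = "coif1",
    roster: FeatureRoster | None = None,
) -> StaticFeatureVector:
    """Full 484-feature static vector for one (already normalised) phase.

    Intensity features are computed on the raw ROI values; texture features
    on the quantised ROI; the 424 wavelet features re-quantise each
    stationary sub-band inside the same mask and re-run the texture bank.
    """
    mask = np.asarray(mask).astype(bool)
    names, cats = static_feature_names(roster)
    values: dict[str, float] = {}
    values.update(intensity_features(np.asarray(phase_volume)[mask]))
    values.update(texture_features(quantize_gray_levels(phase_volume, mask, n_levels)))
    bands = wavelet_decompose(phase_volume, wavelet=wavelet, stationary=True)
    for band_name, band in bands.items():
        feats = texture_features(quantize_gray_levels(band, mask, n_levels))
        values.update({f"{k}_wavelet.{band_name}": v for k, v in feats.items()})
    vec = np.array([values[n] for n in names])
    return StaticFeatureVector(phase_id=phase_id, names=names, values=vec, categories=cats)
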