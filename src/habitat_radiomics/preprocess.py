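"""Volume standardization: isotropic resampling, VOI percentile clipping, z-scoring.

The pipeline order is fixed: resample (linear for images, nearest-neighbor
for masks) -> percentile clipping inside the tumor VOI -> per-patient,
per-sequence z-score standardization. Defaults: 1x1x1 mm target spacing,
(0.5, 99.5) clip percentiles, whole-volume z-score scope, population (1/N)
SD convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk


@dataclass
class PreprocessConfig:
    target_spacing: tuple = (1.0, 1.0, 1.0)
    clip_percentiles: tuple = (0.5, 99.5)
    zscore_scope: str = "whole_volume"  # or "voi"

    def __post_init__(self):
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target spacing must be positive")
        lo, hi = self.clip_percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError("clip percentiles must satisfy 0 <= low < high <= 100")
        if self.zscore_scope not in ("whole_volume", "voi"):
            raise ValueError("zscore_scope must be 'whole_volume' or 'voi'")


def resample(
    volume: np.ndarray, spacing_in, spacing_out, method: str = "linear"
) -> np.ndarray:
    """Resample a 3D volume between voxel spacings.

    Output grid shape is ceil(shape * spacing_in / spacing_out); the output
    sample at index i lies at physical position i * spacing_out in the input
    frame (shared origin at voxel 0). ``method`` is "linear" or "nearest";
    nearest-neighbor on a binary mask returns a binary mask.
    """
    spacing_in = np.asarray(spacing_in, dtype=float)
    spacing_out = np.asarray(spacing_out, dtype=float)
    if np.any(spacing_in <= 0) or np.any(spacing_out <= 0):
        raise ValueError("spacings must be positive")
    if np.allclose(spacing_in, spacing_out):
        return np.asarray(volume).copy()
    in_dtype = volume.dtype
    img = sitk.GetImageFromArray(np.asarray(volume, dtype=float))
    # SimpleITK spacing order is (x, y, z) = reversed numpy axes
    img.SetSpacing(tuple(spacing_in[::-1]))
    out_shape = np.ceil(np.array(volume.shape) * spacing_in / spacing_out).astype(int)
    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}[method]
    res = sitk.Resample(
        img,
        [int(s) for s in out_shape[::-1]],
        sitk.Transform(),
        interp,
        (0.0, 0.0, 0.0),
        tuple(spacing_out[::-1]),
        (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        0.0,
        sitk.sitkFloat64,
    )
    out = sitk.GetArrayFromImage(res)
    if method == "nearest":
        out = out.astype(in_dtype)
    return out


def clip_to_percentiles(
    volume: np.ndarray, mask: np.ndarray, low: float, high: float
) -> np.ndarray:
    """Clip voxel intensities inside ``mask`` to its [P_low, P_high] range.

    Voxels outside the mask are untouched.
    """
    if low >= high:
        raise ValueError("low percentile must be below high percentile")
    mask = mask.astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    vals = volume[mask]
    p_lo, p_hi = np.percentile(vals, [low, high])
    out = volume.astype(float).copy()
    out[mask] = np.clip(vals, p_lo, p_hi)
    return out


def zscore(volume: np.ndarray, mask: np.ndarray | None = None, name: str = "") -> np.ndarray:
    """Standardize to mean 0, SD 1 (population convention) over the scope region.

    ``mask=None`` uses the whole volume. A zero-variance scope raises,
    naming the offending patient/sequence when ``name`` is given.
    """
    scope = np.ones(volume.shape, dtype=bool) if mask is None else mask.astype(bool)
    vals = volume[scope]
    if vals.size < 2:
        raise ValueError(f"z-score scope has fewer than 2 voxels ({name})")
    mu, sd = vals.mean(), vals.std()
    if sd == 0:
        raise ValueError(f"zero variance in z-score scope ({name})")
    return (volume - mu) / sd


def preprocess_study(study, config: PreprocessConfig | None = None):
    """Apply resample -> clip -> z-score to every sequence of a study in place-free form.

    Returns a new study object of the same type with standardized sequences
    and resampled masks.
    """
    import copy

    config = config or PreprocessConfig()
    out = copy.copy(study)
    first_spacing = next(iter(study.sequences.values()))[1]
    mask = resample(
        study.tumor_mask.astype(np.uint8), first_spacing, config.target_spacing, "nearest"
    ).astype(bool)
    rater2 = resample(
        study.tumor_mask_rater2.astype(np.uint8),
        first_spacing,
        config.target_spacing,
        "nearest",
    ).astype(bool)
    seqs = {}
    for seq, (vol, spacing) in study.sequences.items():
        v = resample(vol, spacing, config.target_spacing, "linear")
        v = clip_to_percentiles(v, mask, *config.clip_percentiles)
        scope = mask if config.zscore_scope == "voi" else None
        v = zscore(v, scope, name=f"{study.patient_id}/{seq}")
        seqs[seq] = (v, tuple(config.target_spacing))
    out.sequences = seqs
    out.tumor_mask = mask
    out.tumor_mask_rater2 = rater2
    if study.truth.get("habitat_map") is not None:
        out.truth = dict(study.truth)
        out.truth["habitat_map"] = resample(
            study.truth["habitat_map"].astype(np.int16),
            first_spacing,
            config.target_spacing,
            "nearest",
        )
    return out
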