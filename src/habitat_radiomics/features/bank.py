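"""The radiomics feature bank: 1,037 features per (sequence, region).

Layout: 14 shape descriptors on the original geometry, plus the 93
intensity-based features (18 first-order + 24 GLCM + 14 GLDM + 16 GLRLM +
16 GLSZM + 5 NGTDM) on each of 11 images (original, 8 wavelet subbands,
2 LoG scales): 14 + 93 * 11 = 1,037.

Naming: whole-tumor features are prefixed by the sequence name
(``T2WI_original_glcm_Contrast``); habitat features insert the habitat
region (``DCE_habitat1_wavelet-LLL_firstorder_Mean``). For a cohort with K
habitats the three pools have widths 1,037*3 (conventional), 1,037*3*K
(habitat) and their sum (fusion).

Regions smaller than ``min_region_voxels`` yield missing-flagged vectors
(NaN values plus a recorded reason) rather than silent NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import WAVELET_SUBBANDS, filter_images
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .matrices import (
    discretize,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .shape import SHAPE_NAMES, shape_features

FAMILY_SIZES = {
    "shape": 14,
    "firstorder": 18,
    "glcm": 24,
    "gldm": 14,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
}
INTENSITY_FAMILIES = ("firstorder", "glcm", "gldm", "glrlm", "glszm", "ngtdm")
DEFAULT_FILTERS = (
    "original",
    *[f"wavelet-{sb}" for sb in WAVELET_SUBBANDS],
    "log-sigma-3mm",
    "log-sigma-4mm",
)


@dataclass
class FeatureBankConfig:
    families: tuple = tuple(FAMILY_SIZES)
    filters: tuple = DEFAULT_FILTERS
    bin_count: int = 32
    log_sigmas_mm: tuple = (3.0, 4.0)
    wavelet: str = "coif1"
    min_region_voxels: int = 10

    def __post_init__(self):
        unknown = set(self.families) - set(FAMILY_SIZES)
        if unknown:
            raise ValueError(f"unknown families: {unknown}")
        if self.bin_count < 2:
            raise ValueError("bin_count must be >= 2")


def count_features(config: FeatureBankConfig) -> int:
    """Number of features per (sequence, region). Full default config: 1,037."""
    n_shape = FAMILY_SIZES["shape"] if "shape" in config.families else 0
    n_intensity = sum(
        FAMILY_SIZES[f] for f in config.families if f in INTENSITY_FAMILIES
    )
    return n_shape + n_intensity * len(config.filters)


def feature_names(config: FeatureBankConfig) -> list:
    """Ordered per-(sequence, region) feature names, length = count_features."""
    names = []
    if "shape" in config.families:
        names += [f"original_shape_{n}" for n in SHAPE_NAMES]
    fam_names = {
        "firstorder": FIRSTORDER_NAMES,
        "glcm": _GLCM_NAMES,
        "gldm": _GLDM_NAMES,
        "glrlm": _GLRLM_NAMES,
        "glszm": _GLSZM_NAMES,
        "ngtdm": _NGTDM_NAMES,
    }
    for filt in config.filters:
        for fam in INTENSITY_FAMILIES:
            if fam in config.families:
                names += [f"{filt}_{fam}_{n}" for n in fam_names[fam]]
    return names


_GLCM_NAMES = [
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
]
_GLDM_NAMES = [
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]
_GLRLM_NAMES = [
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]
_GLSZM_NAMES = [
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]
_NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

_FAMILY_FUNCS = {
    "glcm": glcm_features,
    "gldm": gldm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
}


@dataclass
class FeatureVector:
    """One (patient, sequence, region) feature vector; NaN-filled when missing."""

    values: dict
    missing: str | None = None


def _crop_bbox(mask: np.ndarray, arrays: list, margin: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return mask[sl], [a[sl] for a in arrays]


def extract_region_features(
    filtered: dict, mask_region: np.ndarray, spacing, config: FeatureBankConfig
) -> FeatureVector:
    """All configured features for one region from pre-filtered images.

    ``filtered`` maps filter name -> full-grid volume (must cover
    ``config.filters``). Regions below ``min_region_voxels`` return a
    missing-flagged vector with every value NaN.
    """
    names = feature_names(config)
    mask_region = mask_region.astype(bool)
    n = int(mask_region.sum())
    if n < config.min_region_voxels:
        return FeatureVector(
            values={k: float("nan") for k in names},
            missing=f"region has {n} voxels < min_region_voxels={config.min_region_voxels}",
        )
    voxel_volume = float(np.prod(spacing))
    values = {}
    if "shape" in config.families:
        sf = shape_features(mask_region, spacing)
        for fname in SHAPE_NAMES:
            values[f"original_shape_{fname}"] = sf[fname]
    cmask, cvols = _crop_bbox(mask_region, [filtered[f] for f in config.filters])
    for filt, vol in zip(config.filters, cvols):
        disc = discretize(vol, cmask, config.bin_count)
        if "firstorder" in config.families:
            fo = firstorder_features(vol, cmask, voxel_volume, config.bin_count)
            for fname in FIRSTORDER_NAMES:
                values[f"{filt}_firstorder_{fname}"] = fo[fname]
        for fam in ("glcm", "gldm", "glrlm", "glszm", "ngtdm"):
            if fam in config.families:
                ff = _FAMILY_FUNCS[fam](disc)
                for fname, v in ff.items():
                    values[f"{filt}_{fam}_{fname}"] = v
    return FeatureVector(values={k: values[k] for k in names})


def extract_study_features(
    sequences: dict,
    spacing,
    whole_mask: np.ndarray,
    habitat_map: np.ndarray | None,
    n_habitats: int,
    config: FeatureBankConfig,
) -> dict:
    """Flat name -> value dict for one patient across sequences and regions.

    ``sequences`` maps sequence name -> 3D volume (already preprocessed and
    co-registered). Habitat regions come from ``habitat_map`` (labels 1..K
    on tumor voxels); an empty habitat yields missing-flagged columns.
    """
    out = {}
    for seq, vol in sequences.items():
        filtered = filter_images(vol, spacing, config.log_sigmas_mm, config.wavelet)
        filtered = {k: filtered[k] for k in config.filters}
        fv = extract_region_features(filtered, whole_mask, spacing, config)
        for name, v in fv.values.items():
            out[f"{seq}_{name}"] = v
        if habitat_map is not None:
            for k in range(1, n_habitats + 1):
                region = habitat_map == k
                fvk = extract_region_features(filtered, region, spacing, config)
                for name, v in fvk.values.items():
                    out[f"{seq}_habitat{k}_{name}"] = v
    return out


def extract_cohort_tables(
    cohort, habitat_maps: dict, config: FeatureBankConfig, n_habitats: int
) -> dict:
    """Conventional / habitat / fusion feature tables for a whole cohort.

    Returns {"conventional": DataFrame, "habitat": DataFrame,
    "fusion": DataFrame} indexed by patient id. Widths are
    count * n_sequences, count * n_sequences * K and their sum.
    """
    rows = {}
    for study in cohort.studies:
        seqs = {name: vol for name, (vol, _) in study.sequences.items()}
        if len(seqs) < 3:
            raise ValueError(f"patient {study.patient_id} is missing a sequence")
        spacing = next(iter(study.sequences.values()))[1]
        rows[study.patient_id] = extract_study_features(
            seqs,
            spacing,
            study.tumor_mask,
            habitat_maps.get(study.patient_id),
            n_habitats,
            config,
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    habitat_cols = [c for c in table.columns if "_habitat" in c]
    conv_cols = [c for c in table.columns if "_habitat" not in c]
    conventional = table[conv_cols].copy()
    habitat = table[habitat_cols].copy()
    fusion = table.copy()
    conventional.attrs["pool"] = "conventional"
    habitat.attrs["pool"] = "habitat"
    fusion.attrs["pool"] = "fusion"
    return {"conventional": conventional, "habitat": habitat, "fusion": fusion}
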