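"""Synthetic multiparametric breast-MRI cohort with planted habitat structure.

The generator emulates the study conditions the pipeline is designed for: a
cohort of 125 triple-negative breast-cancer patients (66 with axillary
lymph-node metastasis, 59 without), three co-registered sequences (T2WI,
DWI, DCE) at near-isotropic spacing, a tumor mask plus a perturbed
second-rater mask, and a clinical table whose class-conditional
distributions match the reported cohort (e.g. ALN length 18.4 +/- 11.9 mm
in ALNM vs 5.0 +/- 5.9 mm in non-ALNM; washout TIC enriched in ALNM).

Tumors are ellipsoids with a smoothed random boundary containing
``n_habitats_true`` spatially contiguous habitats laid out as thick lateral
sub-lobes (or, optionally, concentric shells): habitat 1 reads as a
necrotic zone (T2-bright, unenhancing), the last habitat as the
vascularized, strongly DCE-enhancing zone. Each habitat has a distinct
multiparametric signature - a per-sequence Gaussian mean plus spatially
correlated texture noise whose amplitude also differs by habitat - and
adjacent habitats blend gradually over a few millimetres. The ALNM label is
coupled to the volume fraction of the high-DCE habitat and to ALN length
through their class-conditional distributions.

Everything is a pure function of the config (fixed seed => byte-identical
cohort).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

SEQUENCES = ("T2WI", "DWI", "DCE")

# class-conditional clinical targets (non-ALNM, ALNM); continuous: (mean, SD)
DEFAULT_CONTINUOUS = {
    "age": {"non_alnm": (47.4, 9.9), "alnm": (50.5, 9.2), "clip_min": 18.0},
    "tumor_length": {"non_alnm": (26.6, 9.6), "alnm": (30.4, 17.7), "clip_min": 5.0},
    "aln_length": {"non_alnm": (5.0, 5.9), "alnm": (18.4, 11.9), "clip_min": 0.0},
    "alb_glb": {"non_alnm": (1.7, 0.3), "alnm": (1.6, 0.3), "clip_min": 0.5},
    "tc": {"non_alnm": (4.4, 0.8), "alnm": (4.8, 1.0), "clip_min": 1.0},
    "hdl_c": {"non_alnm": (1.3, 0.3), "alnm": (1.3, 0.3), "clip_min": 0.3},
    "ldl_c": {"non_alnm": (2.5, 0.7), "alnm": (2.8, 0.7), "clip_min": 0.5},
}
# categorical: level probabilities per class
DEFAULT_CATEGORICAL = {
    "tic": {
        "levels": ("inflow_or_platform", "washout"),
        "non_alnm": (34 / 59, 25 / 59),
        "alnm": (16 / 66, 50 / 66),
    },
    "bi_rads": {
        "levels": ("4a4b", "4c", "5"),
        "non_alnm": (12 / 59, 21 / 59, 26 / 59),
        "alnm": (5 / 66, 12 / 66, 49 / 66),
    },
    "grade": {
        "levels": ("G1_2", "G3"),
        "non_alnm": (35 / 59, 24 / 59),
        "alnm": (14 / 66, 52 / 66),
    },
    "ki67": {
        "levels": ("lt20", "ge20"),
        "non_alnm": (22 / 59, 37 / 59),
        "alnm": (14 / 66, 52 / 66),
    },
    "menopause": {
        "levels": (0, 1),
        "non_alnm": (34 / 59, 25 / 59),
        "alnm": (34 / 66, 32 / 66),
    },
}


@dataclass
class ClinicalRecord:
    age: float
    tumor_length: float
    aln_length: float
    alb_glb: float
    tc: float
    hdl_c: float
    ldl_c: float
    tic: str
    bi_rads: str
    grade: str
    ki67: str
    menopause: int
    alnm: int


@dataclass
class MpMRIStudy:
    """One patient: three co-registered sequences, masks, clinical record."""

    patient_id: str
    sequences: dict  # name -> (volume, spacing)
    tumor_mask: np.ndarray
    tumor_mask_rater2: np.ndarray
    clinical: ClinicalRecord
    truth: dict = field(default_factory=dict)  # planted ground truth


@dataclass
class Cohort:
    studies: list
    split: dict  # patient_id -> "train" | "test"
    split_seed: int

    @property
    def labels(self) -> pd.Series:
        return pd.Series(
            {s.patient_id: s.clinical.alnm for s in self.studies}, name="alnm"
        )

    def ids(self, subset: str | None = None):
        if subset is None:
            return [s.patient_id for s in self.studies]
        return [s.patient_id for s in self.studies if self.split[s.patient_id] == subset]

    def clinical_frame(self) -> pd.DataFrame:
        rows = {s.patient_id: dataclasses.asdict(s.clinical) for s in self.studies}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df["split"] = pd.Series(self.split)
        return df


@dataclass
class SyntheticConfig:
    n_patients: int = 125
    aln_frac: float = 66 / 125
    grid_shape: tuple = (48, 48, 48)
    voxel_spacing: tuple = (1.0, 1.0, 1.0)
    n_habitats_true: int = 3
    # distinct multiparametric signatures per habitat (1 -> K): the necrotic
    # habitat is T2 hyperintense with no enhancement, the hypercellular one
    # is DWI-bright, the vascularized one enhances strongly on DCE; the
    # signatures are deliberately non-collinear (each habitat stands out in
    # a different sequence)
    habitat_intensity_means: dict = field(
        default_factory=lambda: {
            "T2WI": (1.3, -1.0, 0.3),
            "DWI": (-0.9, 1.3, -0.2),
            "DCE": (-1.1, 0.0, 1.4),
        }
    )
    # per-sequence, per-habitat texture noise SD: each habitat is most
    # heterogeneous in a different contrast mechanism
    habitat_noise_sd: dict = field(
        default_factory=lambda: {
            "T2WI": (0.25, 0.55, 0.35),
            "DWI": (0.35, 0.25, 0.55),
            "DCE": (0.55, 0.35, 0.25),
        }
    )
    habitat_texture_scales: tuple = (0.75, 0.75, 0.75)  # noise correlation length, mm
    transition_mm: float = 2.5  # width of the gradual blend between habitats
    background_sd: float = 1.0
    boundary_roughness: float = 0.12
    # habitat layout: "lateral" sub-lobes (zones along a random direction,
    # mildly blended with the radial coordinate) or "concentric" shells;
    # lateral lobes keep every habitat thick and compact
    habitat_geometry: str = "lateral"
    # volume fraction of the high-DCE habitat, (mean, SD) per class
    high_habitat_frac: dict = field(
        default_factory=lambda: {"non_alnm": (0.22, 0.07), "alnm": (0.36, 0.08)}
    )
    # ALNM tumors carry a more angiogenic vascular habitat: its DCE mean is
    # shifted up and its texture noise amplified relative to non-ALNM cases,
    # so the planted class signal lives in the habitat's own intensity and
    # heterogeneity, not only in its volume fraction
    alnm_habitat_effect: dict = field(
        default_factory=lambda: {"dce_mean_shift": 0.28, "noise_scale": 1.18}
    )
    continuous_effects: dict = field(default_factory=lambda: dict(DEFAULT_CONTINUOUS))
    categorical_effects: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORICAL))
    rater2_radius_mm: float = 1.0
    rater2_noise_frac: float = 0.2
    train_frac: float = 0.70
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not 0 < self.aln_frac < 1:
            raise ValueError("aln_frac must be in (0, 1)")
        if not 2 <= self.n_habitats_true <= 10:
            raise ValueError("n_habitats_true must be in [2, 10]")
        if self.habitat_geometry not in ("lateral", "concentric"):
            raise ValueError("habitat_geometry must be 'lateral' or 'concentric'")
        for seq in SEQUENCES:
            for name, table in (
                ("habitat_intensity_means", self.habitat_intensity_means),
                ("habitat_noise_sd", self.habitat_noise_sd),
            ):
                if len(table[seq]) != self.n_habitats_true:
                    raise ValueError(
                        f"{name}[{seq}] must list {self.n_habitats_true} values"
                    )
            if any(s < 0 for s in self.habitat_noise_sd[seq]):
                raise ValueError("noise SDs must be >= 0")


# --------------------------------------------------------------------------
# clinical covariates


@lru_cache(maxsize=256)
def _clipped_normal_location(target_mean: float, sd: float, clip_min: float) -> float:
    """Pre-clip location mu such that E[max(N(mu, sd), clip_min)] = target_mean."""
    if sd == 0:
        return target_mean

    def clipped_mean(mu):
        beta = (mu - clip_min) / sd
        return (
            mu * stats.norm.cdf(beta)
            + clip_min * stats.norm.cdf(-beta)
            + sd * stats.norm.pdf(beta)
        )

    if clipped_mean(target_mean - 6 * sd) > target_mean:
        raise ValueError("clip_min too close to target mean")
    return optimize.brentq(
        lambda mu: clipped_mean(mu) - target_mean,
        target_mean - 6 * sd,
        target_mean + 2 * sd,
        xtol=1e-10,
    )


def _draw_clinical(rng: np.random.Generator, alnm: int, config: SyntheticConfig) -> dict:
    cls = "alnm" if alnm else "non_alnm"
    rec = {}
    for var, eff in config.continuous_effects.items():
        mean, sd = eff[cls]
        clip = eff.get("clip_min", -np.inf)
        mu = _clipped_normal_location(mean, sd, clip) if np.isfinite(clip) else mean
        rec[var] = float(np.maximum(rng.normal(mu, sd), clip))
    for var, eff in config.categorical_effects.items():
        probs = np.asarray(eff[cls], dtype=float)
        probs = probs / probs.sum()
        rec[var] = eff["levels"][rng.choice(len(probs), p=probs)]
    rec["alnm"] = int(alnm)
    return rec


# --------------------------------------------------------------------------
# geometry and intensities


def _correlated_noise(rng, shape, scale_mm, spacing, sd):
    white = rng.standard_normal(shape)
    sigma_vox = np.asarray(scale_mm, dtype=float) / np.asarray(spacing, dtype=float)
    smoothed = ndimage.gaussian_filter(white, sigma=sigma_vox)
    s = smoothed.std()
    return smoothed / s * sd if s > 0 else smoothed


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(sizes)) + 1)


def _make_tumor(rng, config: SyntheticConfig, tumor_length_mm: float):
    """Binary tumor mask and a radial coordinate field used to carve habitats."""
    shape = np.asarray(config.grid_shape)
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    max_radius_mm = (shape * spacing).min() / 2.0 - 3.0 * spacing.max()
    if max_radius_mm <= 0:
        raise ValueError(f"grid {config.grid_shape} cannot contain a tumor")
    radius_mm = float(np.clip(tumor_length_mm / 2.0, 5.5, max_radius_mm))
    axis_scale = rng.uniform(0.8, 1.0, size=3)
    axis_scale /= axis_scale.max()
    radii = radius_mm * axis_scale
    center = shape / 2.0 + rng.uniform(-1.5, 1.5, size=3)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(
        ((g - c) * sp / r) ** 2 for g, c, sp, r in zip(grids, center, spacing, radii)
    )
    r_norm = np.sqrt(r2)
    rough = _correlated_noise(rng, tuple(shape), 3.0, spacing, config.boundary_roughness)
    field = r_norm + rough
    mask = _largest_component(field < 1.0)
    if mask.sum() < 200:
        raise ValueError(
            f"infeasible geometry: tumor of {int(mask.sum())} voxels < 200 on grid {config.grid_shape}"
        )
    return mask, field


def _carve_habitats(rng, mask, field, config: SyntheticConfig, high_frac: float):
    """Habitat labels 1..K on tumor voxels; habitat K (high DCE) has volume
    fraction ~ ``high_frac``, the rest of the tumor is split evenly.

    "lateral" geometry orders voxels along a random direction through the
    tumor (thick compact sub-lobes); "concentric" orders them by the radial
    boundary field (onion shells). Quantile thresholds fix the fractions.
    """
    k = config.n_habitats_true
    inner = 1.0 - high_frac
    fracs = [inner / (k - 1)] * (k - 1) + [high_frac]
    qs = np.cumsum(fracs)[:-1]
    if config.habitat_geometry == "lateral":
        g = rng.standard_normal(3)
        g /= np.linalg.norm(g)
        idx = np.argwhere(mask).astype(float)
        proj = (idx - idx.mean(axis=0)) @ g
        base = (proj - proj.mean()) / (proj.std() + 1e-12)
    else:
        base = field[mask]
        base = (base - base.mean()) / (base.std() + 1e-12)
    scores = base + 0.1 * rng.standard_normal(base.size)
    cuts = np.quantile(scores, qs)
    labels = np.searchsorted(cuts, scores, side="right") + 1
    hab = np.zeros(mask.shape, dtype=np.int16)
    hab[mask] = labels
    return hab


def _render_sequences(rng, mask, habitats, config: SyntheticConfig, alnm: int = 0) -> dict:
    """Per-habitat Gaussian mean + correlated texture, blended gradually.

    Habitat membership is softened with distance-decay weights
    exp(-d_k / transition_mm) so adjacent habitats blend over a few
    millimetres, as real tissue interfaces do, instead of jumping at a
    sharp voxel boundary.
    """
    spacing = config.voxel_spacing
    kk = config.n_habitats_true
    weights = []
    for k in range(1, kk + 1):
        d = ndimage.distance_transform_edt(habitats != k, sampling=spacing)
        weights.append(np.exp(-d / max(config.transition_mm, 1e-6)))
    w = np.stack(weights)
    w /= w.sum(axis=0)
    out = {}
    for seq in SEQUENCES:
        vol = _correlated_noise(rng, mask.shape, 1.0, spacing, config.background_sd)
        means = config.habitat_intensity_means[seq]
        amps = config.habitat_noise_sd[seq]
        tumor = np.zeros(mask.shape)
        for k in range(1, kk + 1):
            mean_k = means[k - 1]
            amp_k = amps[k - 1]
            if alnm and k == kk:  # the vascular habitat of an ALNM tumor
                if seq == "DCE":
                    mean_k = mean_k + config.alnm_habitat_effect["dce_mean_shift"]
                amp_k = amp_k * config.alnm_habitat_effect["noise_scale"]
            tex = _correlated_noise(
                rng,
                mask.shape,
                config.habitat_texture_scales[k - 1],
                spacing,
                amp_k,
            )
            tumor += w[k - 1] * (mean_k + tex)
        vol[mask] = tumor[mask]
        out[seq] = (vol.astype(np.float32).astype(float), tuple(spacing))
    return out


def perturb_mask(
    mask: np.ndarray,
    spacing,
    radius_mm: float = 1.0,
    noise_frac: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Emulate a second rater: morphological dilation/erosion plus boundary noise.

    Deterministic given ``seed``; raises if the perturbation would empty the
    mask. With radius 0 and noise 0 the input is returned unchanged.
    """
    mask = mask.astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    rng = np.random.default_rng(seed)
    out = mask.copy()
    if radius_mm > 0:
        # locally varying boundary displacement: push the zero level set of the
        # signed distance in/out by up to ~radius_mm, modulated by a smooth
        # random field (a reader deviates locally, not by a global margin)
        sp = np.asarray(spacing, dtype=float)
        d_in = ndimage.distance_transform_edt(mask, sampling=sp)
        d_out = ndimage.distance_transform_edt(~mask, sampling=sp)
        signed = np.where(mask, d_in, -d_out)
        u = _correlated_noise(rng, mask.shape, 6.0, sp, 1.0)
        out = (signed + radius_mm * u) > 0
    if noise_frac > 0:
        boundary_in = out & ~ndimage.binary_erosion(out)
        boundary_out = ndimage.binary_dilation(out) & ~out
        for boundary in (boundary_in, boundary_out):
            idx = np.argwhere(boundary)
            if idx.size == 0:
                continue
            n_flip = int(round(noise_frac * idx.shape[0]))
            if n_flip > 0:
                pick = rng.choice(idx.shape[0], size=n_flip, replace=False)
                for z, y, x in idx[pick]:
                    out[z, y, x] = ~out[z, y, x]
    out = _largest_component(out)
    if out.sum() == 0 or not (out & mask).any():
        raise ValueError("perturbation emptied the mask (no overlap with the original)")
    return out


def split_cohort(labels: dict, train_frac: float = 0.70, seed: int = 0) -> dict:
    """Label-stratified random train/test split.

    The train set holds floor(train_frac * n) patients; per-class quotas are
    floor(train_frac * n_class) with remainders assigned by largest
    fractional part (RNG tie-break). Both classes must have >= 2 patients.
    """
    rng = np.random.default_rng(seed)
    ids = np.array(list(labels.keys()))
    y = np.array([labels[i] for i in ids])
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 patients")
    n_train_total = int(np.floor(train_frac * ids.size))
    quotas = {}
    fracparts = []
    for c in classes:
        exact = train_frac * (y == c).sum()
        quotas[c] = int(np.floor(exact))
        fracparts.append((exact - quotas[c], rng.random(), c))
    remaining = n_train_total - sum(quotas.values())
    for _, _, c in sorted(fracparts, reverse=True)[:remaining]:
        quotas[c] += 1
    split = {}
    for c in classes:
        members = ids[y == c]
        perm = rng.permutation(members.size)
        train_ids = set(members[perm[: quotas[c]]])
        for pid in members:
            split[pid] = "train" if pid in train_ids else "test"
    return split


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate the full synthetic cohort (volumes, masks, clinical table, split)."""
    rng = np.random.default_rng(config.seed)
    n_pos = int(round(config.aln_frac * config.n_patients))
    labels = np.array([1] * n_pos + [0] * (config.n_patients - n_pos))
    rng.shuffle(labels)
    studies = []
    for i, alnm in enumerate(labels):
        pid = f"P{i + 1:03d}"
        rec = _draw_clinical(rng, int(alnm), config)
        cls = "alnm" if alnm else "non_alnm"
        fm, fs = config.high_habitat_frac[cls]
        k = config.n_habitats_true
        high_frac = float(np.clip(rng.normal(fm, fs), 0.05, 0.9 - 0.05 * (k - 1)))
        mask, fieldv = _make_tumor(rng, config, rec["tumor_length"])
        habitats = _carve_habitats(rng, mask, fieldv, config, high_frac)
        sequences = _render_sequences(rng, mask, habitats, config, alnm=int(alnm))
        rater2 = perturb_mask(
            mask,
            config.voxel_spacing,
            config.rater2_radius_mm,
            config.rater2_noise_frac,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        studies.append(
            MpMRIStudy(
                patient_id=pid,
                sequences=sequences,
                tumor_mask=mask,
                tumor_mask_rater2=rater2,
                clinical=ClinicalRecord(**rec),
                truth={
                    "habitat_map": habitats,
                    "high_habitat_frac": high_frac,
                },
            )
        )
    split_seed = int(np.random.default_rng(config.seed + 1).integers(0, 2**31 - 1))
    split = split_cohort(
        {s.patient_id: s.clinical.alnm for s in studies},
        config.train_frac,
        seed=split_seed,
    )
    return Cohort(studies=studies, split=split, split_seed=split_seed)


# --------------------------------------------------------------------------
# on-disk representation


def write_cohort(cohort: Cohort, out_dir, config: SyntheticConfig | None = None):
    """Write per-patient NIfTI volumes/masks, the clinical CSV and a manifest."""
    import nibabel as nib

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for study in cohort.studies:
        pdir = out / "images" / study.patient_id
        pdir.mkdir(exist_ok=True)
        for seq, (vol, spacing) in study.sequences.items():
            affine = np.diag(list(spacing) + [1.0])
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), pdir / f"{seq}.nii.gz")
        affine = np.diag(list(next(iter(study.sequences.values()))[1]) + [1.0])
        nib.save(
            nib.Nifti1Image(study.tumor_mask.astype(np.uint8), affine),
            pdir / "mask.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(study.tumor_mask_rater2.astype(np.uint8), affine),
            pdir / "mask_rater2.nii.gz",
        )
    cohort.clinical_frame().to_csv(out / "clinical.csv", index_label="patient_id")
    manifest = {
        "n_patients": len(cohort.studies),
        "split_seed": cohort.split_seed,
        "config": dataclasses.asdict(config) if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
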