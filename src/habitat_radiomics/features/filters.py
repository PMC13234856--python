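"""Image filters feeding the feature bank: wavelet subbands and LoG responses.

The wavelet decomposition is a single-level undecimated (stationary) 3D
transform whose 8 subbands are all low/high-pass combinations along the
three axes, named ``wavelet-LLL`` ... ``wavelet-HHH`` (the standard
radiomics layout that, together with two LoG scales, yields 11 images per
sequence). Default basis: coif1.

The LoG response is scale-normalized, response = sigma^2 * Laplacian(G_sigma * I),
with sigma given in millimetres and converted to voxels via the spacing.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

WAVELET_SUBBANDS = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]


def wavelet_subbands(volume: np.ndarray, wavelet: str = "coif1") -> dict:
    """8 single-level stationary-wavelet subbands at input resolution.

    Volumes with odd extents are edge-padded to even and cropped back.
    Subband names map axis order 0,1,2 to the letters left to right
    ('a' -> L, 'd' -> H).
    """
    volume = np.asarray(volume, dtype=float)
    if min(volume.shape) < 2:
        raise ValueError("volume too small for a wavelet transform")
    pads = [(0, s % 2) for s in volume.shape]
    padded = np.pad(volume, pads, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1, start_level=0)[0]
    crop = tuple(slice(0, s) for s in volume.shape)
    out = {}
    for key, arr in coeffs.items():
        name = "wavelet-" + "".join("L" if c == "a" else "H" for c in key)
        out[name] = arr[crop]
    return {name: out[f"wavelet-{sb}"] for sb in WAVELET_SUBBANDS for name in [f"wavelet-{sb}"]}


def log_filter(volume: np.ndarray, spacing, sigma_mm: float) -> np.ndarray:
    """Scale-normalized Laplacian-of-Gaussian response at one scale."""
    spacing = np.asarray(spacing, dtype=float)
    sigma_vox = sigma_mm / spacing
    return sigma_mm**2 * ndimage.gaussian_laplace(
        np.asarray(volume, dtype=float), sigma=sigma_vox
    )


def filter_images(volume: np.ndarray, spacing, sigmas=(3.0, 4.0), wavelet: str = "coif1") -> dict:
    """All filtered versions of ``volume``: original + 8 wavelet + len(sigmas) LoG."""
    out = {"original": np.asarray(volume, dtype=float)}
    out.update(wavelet_subbands(volume, wavelet))
    for s in sigmas:
        out[f"log-sigma-{s:g}mm"] = log_filter(volume, spacing, s)
    return out
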