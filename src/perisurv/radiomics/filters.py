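"""Image filters feeding the derived feature classes: wavelet and LoG.

The wavelet bank is a one-level stationary (undecimated) 3D decomposition
into the 8 sub-bands LLL..HHH; the family defaults to coif1.  The LoG bank
is a scale-normalized (sigma^2-weighted) Gaussian second-derivative
convolution with sigma specified in millimetres, so responses of the five
scales are comparable and the strongest response picks out structures of
matching physical size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["FilterBank", "wavelet_subbands", "log_filtered"]


@dataclass
class FilterBank:
    """One-level wavelet decomposition plus a bank of LoG scales (mm)."""

    wavelet: str = "coif1"
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigmas must be positive")
        pywt.Wavelet(self.wavelet)  # validates the family name


def wavelet_subbands(image: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """The 8 same-size sub-bands (LLL..HHH) of a one-level stationary 3D DWT.

    Axes are padded (edge mode) to even length for the transform and
    cropped back, so sub-bands align voxel-for-voxel with the input.
    """
    img = np.asarray(image, dtype=np.float64)
    if any(n < 2 for n in img.shape):
        raise ValueError(f"image too small for a wavelet level: shape {img.shape}")
    pad = [(0, n % 2) for n in img.shape]
    padded = np.pad(img, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1, start_level=0)[0]
    out = {}
    for key, arr in coeffs.items():
        name = key.upper().replace("A", "L").replace("D", "H")
        out[f"wavelet-{name}"] = arr[tuple(slice(0, n) for n in img.shape)]
    return out


def log_filtered(image: np.ndarray, sigma_mm: float, spacing) -> np.ndarray:
    """Scale-normalized Laplacian-of-Gaussian response at one physical scale.

    The image mean (DC) is removed before filtering: a perfect LoG kernel
    has zero DC response, but a truncated one does not, so subtracting the
    mean makes a constant image map to exactly zero without needing an
    extravagant kernel support.
    """
    img = np.asarray(image, dtype=np.float64)
    sigma_vox = [sigma_mm / s for s in spacing]
    return sigma_mm**2 * ndimage.gaussian_laplace(img - img.mean(), sigma=sigma_vox)
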