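"""Intensity normalization and fixed-bin-width gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizationParams", "normalize_image", "normalize_and_discretize"]


@dataclass
class DiscretizationParams:
    """Fixed-bin-width discretization settings.

    ``normalize`` applies a whole-image z-score scaled by ``normalize_scale``
    before binning, so a bin width of 25 spans a quarter of one image SD.
    """

    bin_width: float = 25.0
    normalize: bool = True
    normalize_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if self.normalize_scale <= 0:
            raise ValueError("normalization scale must be positive")


def normalize_image(image: np.ndarray, params: DiscretizationParams) -> np.ndarray:
    """Whole-image z-score times the fixed scale factor (identity when off)."""
    img = np.asarray(image, dtype=np.float64)
    if not params.normalize:
        return img
    sd = img.std()
    if sd == 0:
        return np.zeros_like(img)
    return (img - img.mean()) / sd * params.normalize_scale


def discretize_fixed_width(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Map intensities to gray levels 1..Ng: level = floor((x - min)/w) + 1.

    The maximum value falls in the top bin by construction (its level is
    the level count, never an overflow bin).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty ROI: nothing to discretize")
    levels = np.floor((v - v.min()) / bin_width).astype(np.int64) + 1
    return levels, int(levels.max())


def normalize_and_discretize(
    image: np.ndarray, mask: np.ndarray, params: DiscretizationParams
) -> tuple[np.ndarray, int]:
    """Gray-level map of an ROI after (optional) normalization and binning.

    Returns an integer array with levels 1..Ng inside the mask and 0
    outside, plus the level count Ng.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty ROI")
    norm = normalize_image(image, params)
    levels, n_levels = discretize_fixed_width(norm[m], params.bin_width)
    out = np.zeros(m.shape, dtype=np.int64)
    out[m] = levels
    return out, n_levels
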