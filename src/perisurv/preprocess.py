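"""Spatial and intensity standardization before feature extraction and network input.

Volumes are resampled to isotropic 1 mm voxels with cubic B-spline
interpolation; masks with nearest-neighbour interpolation (which keeps them
strictly binary).  Network inputs are tight tumor bounding boxes rescaled to
a fixed cube by trilinear interpolation and z-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import CTVolume

__all__ = ["NetworkInputBlock", "resample_isotropic", "resample_mask", "crop_resize_roi"]

#: z-normalization tolerance on the output block (contract of NetworkInputBlock)
_ZNORM_TOL = 1e-5


@dataclass
class NetworkInputBlock:
    """A fixed-size z-normalized intensity cube feeding the survival network."""

    data: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"block must be a cube, got shape {self.data.shape}")
        sd = self.data.std()
        if sd > 0 and (abs(self.data.mean()) > _ZNORM_TOL or abs(sd - 1.0) > _ZNORM_TOL):
            raise ValueError("block is not z-normalized")


def _to_sitk(volume: CTVolume) -> sitk.Image:
    # our arrays are (x, y, z); SimpleITK's GetImageFromArray expects (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(volume.data, (2, 1, 0))))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    return img


def _from_sitk(img: sitk.Image) -> CTVolume:
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return CTVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def _resample(volume: CTVolume, target_spacing: float, interpolator) -> CTVolume:
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    img = _to_sitk(volume)
    new_size = [max(int(round(n * s / target_spacing)), 1) for n, s in zip(volume.shape, volume.spacing)]
    # centre-align the output grid inside the physical extent: keeps the
    # resample unbiased at both ends (and the identity case exact)
    new_origin = tuple(
        o + 0.5 * (s * (n - 1) - target_spacing * (m - 1))
        for o, s, n, m in zip(volume.origin, volume.spacing, volume.shape, new_size)
    )
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing((target_spacing,) * 3)
    res.SetSize(new_size)
    res.SetOutputOrigin(new_origin)
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(interpolator)
    res.SetDefaultPixelValue(float(np.min(volume.data)))
    return _from_sitk(res.Execute(img))


def resample_isotropic(volume: CTVolume, target_spacing: float = 1.0) -> CTVolume:
    """Resample a CT volume to isotropic voxels with cubic B-spline interpolation.

    The output grid covers the same physical extent (within one voxel) and
    has spacing exactly ``(target_spacing,) * 3``.
    """
    return _resample(volume, target_spacing, sitk.sitkBSpline)


def resample_mask(mask: CTVolume, target_spacing: float = 1.0) -> CTVolume:
    """Resample a binary mask with nearest-neighbour interpolation.

    Raises if the input is not strictly binary; the output is returned as a
    uint8 volume with values in {0, 1}.
    """
    vals = np.unique(mask.data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask is not binary: values {vals[:10]}")
    m = CTVolume(np.asarray(mask.data, dtype=np.uint8), mask.spacing, mask.origin)
    out = _resample(m, target_spacing, sitk.sitkNearestNeighbor)
    out.data = (out.data > 0.5).astype(np.uint8)
    return out


def _trilinear_resize(block: np.ndarray, out_shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear resize where output index j samples input coordinate j * n_in / n_out.

    This plain scale convention makes integer zoom factors exact: at 2x
    upsampling every even output voxel reproduces a source voxel.  Samples
    beyond the last voxel centre are clamped (edge replication).
    """
    coords = np.meshgrid(
        *[np.arange(m) * (n / m) for n, m in zip(block.shape, out_shape)],
        indexing="ij",
    )
    return ndimage.map_coordinates(np.asarray(block, dtype=np.float64), coords, order=1, mode="nearest")


def zscore_block(block: np.ndarray) -> np.ndarray:
    """Z-normalize; a zero-SD (constant) block maps to all zeros."""
    block = np.asarray(block, dtype=np.float64)
    sd = block.std()
    if sd == 0:
        return np.zeros_like(block)
    return (block - block.mean()) / sd


def crop_resize_roi(
    volume: CTVolume,
    mask: CTVolume,
    block_size: int = 64,
    mask_background: bool = False,
    subject_id: str = "",
) -> NetworkInputBlock:
    """Crop the tight tumor bounding box, resize to a cube, and z-normalize.

    By default non-tumor voxels inside the box keep their intensities
    (``mask_background=True`` zeroes them instead — exposed because the
    box-versus-masked choice is a genuinely open design point).
    """
    m = np.asarray(mask.data) > 0
    if not m.any():
        raise ValueError("empty mask: nothing to crop")
    if volume.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    sl = ndimage.find_objects(m.astype(np.uint8))[0]
    box = np.asarray(volume.data, dtype=np.float64)[sl]
    if mask_background:
        box = np.where(m[sl], box, 0.0)
    resized = _trilinear_resize(box, (block_size,) * 3)
    return NetworkInputBlock(zscore_block(resized), subject_id=subject_id)
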