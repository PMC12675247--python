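"""Core containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["CTVolume"]


@dataclass
class CTVolume:
    """A 3D intensity volume with physical voxel spacing.

    Arrays are indexed ``(x, y, z)`` in the patient space of the NIfTI
    affine; spacing and origin are in millimetres.  This convention is
    enforced once here and assumed by every downstream module.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise ValueError(f"degenerate volume shape {self.data.shape}: each axis needs >= 2 voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "CTVolume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(s) for s in np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
        origin = tuple(float(o) for o in aff[:3, 3])
        return cls(np.asarray(img.dataobj), spacing, origin)
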