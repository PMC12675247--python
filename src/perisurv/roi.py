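"""Peritumoral region construction at millimetre-calibrated distances.

Expansion is defined through the exact Euclidean distance transform:
a voxel belongs to the d-mm expansion iff the distance from its centre to
the nearest foreground voxel centre is at most d.  This is anisotropy-safe
and matches the "expansion distance" semantics of peritumoral radiomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CTVolume

__all__ = ["ROISet", "expand_mask", "peritumoral_ring", "build_roi_set"]


def _as_bool(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, CTVolume) else np.asarray(mask)
    if not np.all(np.isin(np.unique(data), (0, 1))):
        raise ValueError("mask must be binary")
    return data.astype(bool)


def expand_mask(mask, d_mm: float, spacing: tuple[float, float, float] | None = None) -> np.ndarray:
    """Dilate a binary mask to all voxels within ``d_mm`` (centre-to-centre).

    ``spacing`` is taken from the mask when it is a :class:`CTVolume`.
    The expansion is clipped at the image bounds.
    """
    if d_mm < 0:
        raise ValueError("expansion distance must be nonnegative")
    if spacing is None:
        if not isinstance(mask, CTVolume):
            raise ValueError("spacing required when mask is a plain array")
        spacing = mask.spacing
    m = _as_bool(mask)
    if d_mm == 0 or not m.any():
        return m.copy()
    dist = ndimage.distance_transform_edt(~m, sampling=spacing)
    return dist <= d_mm + 1e-9


def peritumoral_ring(
    gtv, d_mm: float, spacing=None, body_mask=None
) -> np.ndarray:
    """The shell within ``d_mm`` of the GTV, excluding the GTV itself.

    Optionally intersected with a body/valid-region mask.  An empty result
    (tumor flush against the volume edge, or body mask excluding the whole
    shell) is rejected with a diagnostic.
    """
    g = _as_bool(gtv)
    if not g.any():
        raise ValueError("empty GTV")
    ring = expand_mask(gtv, d_mm, spacing) & ~g
    if body_mask is not None:
        ring &= _as_bool(body_mask)
    if not ring.any():
        raise ValueError(
            f"peritumoral ring at {d_mm} mm is empty after clipping; "
            "the tumor may touch the volume edge or the body mask may be too tight"
        )
    return ring


@dataclass
class ROISet:
    """GTV plus peritumoral rings keyed by expansion distance (mm)."""

    gtv: np.ndarray
    rings: dict[float, np.ndarray]
    spacing: tuple[float, float, float]
    dilated: dict[float, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d, ring in self.rings.items():
            if ring.shape != self.gtv.shape:
                raise ValueError(f"ring at {d} mm is on a different grid")
            if np.any(ring & self.gtv.astype(bool)):
                raise ValueError(f"ring at {d} mm overlaps the GTV")

    def regions(self) -> dict[str, np.ndarray]:
        """Named region masks: 'intratumoral' plus 'peri<d>mm' per ring."""
        out = {"intratumoral": self.gtv.astype(bool)}
        for d in sorted(self.rings):
            out[f"peri{d:g}mm"] = self.rings[d]
        return out


def build_roi_set(
    gtv: CTVolume, distances=(3.0, 6.0, 9.0), body_mask=None
) -> ROISet:
    """Construct the GTV + ring set used throughout the pipeline."""
    g = _as_bool(gtv)
    rings = {}
    dilated = {}
    for d in distances:
        dil = expand_mask(gtv, d)
        rings[float(d)] = peritumoral_ring(gtv, d, body_mask=body_mask)
        dilated[float(d)] = dil
    return ROISet(g, rings, gtv.spacing, dilated)
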