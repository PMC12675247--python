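"""Per-region assembly of the full 1316-feature vector.

Feature names encode provenance as ``<filter>__<family>__<feature>``
(``original`` for the unfiltered image; first-order has family ``firstorder``,
shape ``shape``); :func:`extract_all` prefixes the region, giving the
``<region>__<filter>__<family>__<feature>`` columns of the feature table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..core import CTVolume
from ..roi import ROISet
from .discretize import DiscretizationParams, discretize_fixed_width, normalize_image
from .filters import FilterBank, log_filtered, wavelet_subbands
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import TEXTURE_NAMES, texture_features

log = logging.getLogger(__name__)

__all__ = ["extract_features", "extract_all", "feature_names", "FEATURE_COUNT"]

#: inventory: 18 first-order + 14 shape + 75 texture + 8*93 wavelet + 5*93 LoG
FEATURE_COUNT = 18 + 14 + 75 + 8 * 93 + 5 * 93


def feature_names(bank: FilterBank | None = None) -> list[str]:
    """The ordered 1316 feature names (no region prefix)."""
    bank = bank or FilterBank()
    names = [f"original__firstorder__{n}" for n in FIRST_ORDER_NAMES]
    names += [f"original__shape__{n}" for n in SHAPE_NAMES]
    names += [f"original__{n}" for n in TEXTURE_NAMES]
    for band in _wavelet_band_names(bank.wavelet):
        names += [f"{band}__firstorder__{n}" for n in FIRST_ORDER_NAMES]
        names += [f"{band}__{n}" for n in TEXTURE_NAMES]
    for sigma in bank.log_sigmas_mm:
        tag = _log_tag(sigma)
        names += [f"{tag}__firstorder__{n}" for n in FIRST_ORDER_NAMES]
        names += [f"{tag}__{n}" for n in TEXTURE_NAMES]
    return names


def _wavelet_band_names(wavelet: str) -> list[str]:
    return [
        f"wavelet-{a}{b}{c}" for c in "LH" for b in "LH" for a in "LH"
    ]


def _log_tag(sigma: float) -> str:
    return f"log-sigma-{sigma:g}mm"


def _roi_block(image: np.ndarray, mask: np.ndarray, margin: int):
    """Crop image+mask to the mask bounding box plus a filter-support margin."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return image[sl], mask[sl]


def _intensity_texture(values: np.ndarray, mask: np.ndarray,
                       params: DiscretizationParams, voxel_volume: float) -> dict[str, float]:
    """First-order + texture (93 features) of one (filtered) image over one ROI."""
    levels_flat, n_levels = discretize_fixed_width(values, params.bin_width)
    # texture matrices only see the region: crop to its tight bounding box
    # (C-order restriction to a box preserves the ROI voxel order)
    idx = np.argwhere(mask)
    sl = tuple(slice(a, b + 1) for a, b in zip(idx.min(axis=0), idx.max(axis=0)))
    level_map = np.zeros(mask[sl].shape, dtype=np.int64)
    level_map[mask[sl]] = levels_flat
    out = {f"firstorder__{k}": v for k, v in
           first_order_features(values, levels_flat, voxel_volume).items()}
    out.update(texture_features(level_map, n_levels))
    return out


def extract_features(
    volume: CTVolume,
    mask: np.ndarray,
    params: DiscretizationParams | None = None,
    bank: FilterBank | None = None,
    filtered_cache: dict[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """The complete 1316-feature vector of one region.

    ``filtered_cache`` may hold precomputed filter responses of the (full)
    normalized image, keyed by the filter tag; :func:`extract_all` uses it
    to share filter passes across regions of the same subject.
    """
    params = params or DiscretizationParams()
    bank = bank or FilterBank()
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty region")

    voxel_volume = volume.voxel_volume_mm3
    norm = normalize_image(np.asarray(volume.data, dtype=np.float64), params)

    out: dict[str, float] = {}
    vals = norm[m]
    for k, v in _intensity_texture(vals, m, params, voxel_volume).items():
        out[f"original__{k}"] = v
    # shape only depends on the mask
    sh = shape_features(m, volume.spacing)
    for k in SHAPE_NAMES:
        out[f"original__shape__{k}"] = sh[k]

    if filtered_cache is None:
        filtered_cache = compute_filter_bank(norm, volume.spacing, bank)
    for band in _wavelet_band_names(bank.wavelet):
        arr = filtered_cache[band]
        for k, v in _intensity_texture(arr[m], m, params, voxel_volume).items():
            out[f"{band}__{k}"] = v
    for sigma in bank.log_sigmas_mm:
        tag = _log_tag(sigma)
        arr = filtered_cache[tag]
        for k, v in _intensity_texture(arr[m], m, params, voxel_volume).items():
            out[f"{tag}__{k}"] = v

    if len(out) != FEATURE_COUNT:  # pragma: no cover - inventory safety net
        raise RuntimeError(f"feature inventory mismatch: {len(out)} != {FEATURE_COUNT}")
    out = {k: out[k] for k in feature_names(bank)}  # canonical column order
    if not all(np.isfinite(v) for v in out.values()):
        bad = [k for k, v in out.items() if not np.isfinite(v)]
        raise RuntimeError(f"non-finite features: {bad[:5]}")
    return out


def compute_filter_bank(norm_image: np.ndarray, spacing, bank: FilterBank) -> dict[str, np.ndarray]:
    """All filter responses of a normalized image, keyed by filter tag."""
    cache = dict(wavelet_subbands(norm_image, bank.wavelet))
    for sigma in bank.log_sigmas_mm:
        cache[_log_tag(sigma)] = log_filtered(norm_image, sigma, spacing)
    return cache


def extract_all(
    volume: CTVolume,
    roi_set: ROISet,
    params: DiscretizationParams | None = None,
    bank: FilterBank | None = None,
    margin: int = 24,
) -> pd.DataFrame:
    """One row of 1316 features per region (intratumoral + each ring).

    The volume is cropped to the union of all regions plus a margin that
    covers the filter supports; filters run once per subject and are shared
    across regions.  Empty regions are skipped with a logged warning.
    """
    params = params or DiscretizationParams()
    bank = bank or FilterBank()
    regions = roi_set.regions()
    union = np.zeros(volume.shape, dtype=bool)
    for m in regions.values():
        union |= m.astype(bool)
    if not union.any():
        raise ValueError("all regions empty")
    img, _ = _roi_block(np.asarray(volume.data, dtype=np.float64), union, margin)
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, union.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))

    # normalization statistics come from the whole image, then crop
    norm_full = normalize_image(np.asarray(volume.data, dtype=np.float64), params)
    norm = norm_full[sl]
    sub = CTVolume(norm, volume.spacing)
    cache = compute_filter_bank(norm, volume.spacing, bank)
    no_norm = DiscretizationParams(bin_width=params.bin_width, normalize=False)

    rows = {}
    for name, m in regions.items():
        mc = m.astype(bool)[sl]
        if not mc.any():
            log.warning("region %s is empty; row skipped", name)
            continue
        rows[name] = extract_features(sub, mc, no_norm, bank, filtered_cache=cache)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return df
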