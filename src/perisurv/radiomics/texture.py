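"""The 75 IBSI texture features: GLCM, GLRLM, GLSZM, NGTDM, GLDM.

Conventions: gray-level co-occurrence at Chebyshev distance 1 over the 13
unique 3D directions with symmetric accumulation and feature-then-average
aggregation; run-length matrices over the same 13 directions (feature
averaged); size zones and dependence/tone neighbourhoods use the full
26-neighbourhood.  Zero-variance guards (single gray level) return the
documented constants (GLCM correlation and MCC -> 1, the information
measures -> 0, NGTDM contrast/busyness -> 0) rather than NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "TEXTURE_NAMES",
    "texture_features",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "ngtdm_matrix",
    "gldm_matrix",
    "DIRECTIONS_13",
    "OFFSETS_26",
]

#: the 13 unique direction vectors of the 26-neighbourhood (one per +/- pair)
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: all 26 neighbour offsets
OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis", "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

TEXTURE_NAMES = tuple(
    [f"glcm__{n}" for n in GLCM_NAMES]
    + [f"glrlm__{n}" for n in GLRLM_NAMES]
    + [f"glszm__{n}" for n in GLSZM_NAMES]
    + [f"ngtdm__{n}" for n in NGTDM_NAMES]
    + [f"gldm__{n}" for n in GLDM_NAMES]
)


def _shift(arr: np.ndarray, offset, fill=0):
    """Shift a 3D array by an integer offset, filling vacated entries."""
    out = np.full_like(arr, fill)
    src = tuple(slice(max(-o, 0), arr.shape[a] - max(o, 0)) for a, o in enumerate(offset))
    dst = tuple(slice(max(o, 0), arr.shape[a] + min(o, 0)) for a, o in enumerate(offset))
    out[dst] = arr[src]
    return out


# ---------------------------------------------------------------------------
# matrices


def glcm_matrix(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Symmetric co-occurrence matrix for one direction (counts, not normalized)."""
    a = levels
    b = _shift(levels, tuple(-d for d in direction))
    valid = (a > 0) & (b > 0)
    idx = (a[valid] - 1) * n_levels + (b[valid] - 1)
    p = np.bincount(idx, minlength=n_levels * n_levels).astype(np.float64)
    p = p.reshape(n_levels, n_levels)
    return p + p.T


def glrlm_matrix(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length matrix for one direction (rows: level, cols: run length).

    Uses the segment-count identity: with S_l(g) = number of positions that
    start a same-level segment of length >= l (maximal or not), the number
    of maximal runs of length exactly l is S_l - 2 S_{l+1} + S_{l+2}.
    """
    a = levels
    seg = a > 0  # segment-of-length-l indicator, grown iteratively
    s_counts = []  # s_counts[l-1][g-1] = S_l(g)
    l = 1
    while seg.any():
        s_counts.append(np.bincount(a[seg] - 1, minlength=n_levels).astype(np.float64))
        sh = _shift(a, tuple(-l * d for d in direction))
        seg = seg & (sh == a)
        l += 1
    max_l = len(s_counts)
    s = np.zeros((max_l + 2, n_levels))
    s[:max_l] = np.asarray(s_counts)
    mat = (s[:max_l] - 2 * s[1 : max_l + 1] + s[2 : max_l + 2]).T
    # trim trailing all-zero run lengths
    nz = np.nonzero(mat.sum(axis=0))[0]
    return mat[:, : nz[-1] + 1] if len(nz) else mat[:, :1]


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix: 26-connected zones per gray level."""
    structure = np.ones((3, 3, 3), dtype=int)
    sizes_per_level: list[np.ndarray] = []
    max_size = 1
    for g in range(1, n_levels + 1):
        lab, n = ndimage.label(levels == g, structure=structure)
        if n == 0:
            sizes_per_level.append(np.array([], dtype=np.int64))
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    mat = np.zeros((n_levels, max_size), dtype=np.float64)
    for g, sizes in enumerate(sizes_per_level):
        for s in sizes:
            mat[g, s - 1] += 1.0
    return mat


def _neighbourhood_pass(levels: np.ndarray):
    """One pass over the 26 offsets: neighbour sums/counts and equal-level counts."""
    in_roi = levels > 0
    nbr_sum = np.zeros(levels.shape, dtype=np.float64)
    nbr_cnt = np.zeros(levels.shape, dtype=np.float64)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        sh = _shift(levels, off)
        present = sh > 0
        nbr_sum += sh
        nbr_cnt += present
        dep += in_roi & present & (sh == levels)
    return in_roi, nbr_sum, nbr_cnt, dep


def ngtdm_matrix(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighbourhood gray-tone difference: per level, (n_i, s_i)."""
    in_roi, nbr_sum, nbr_cnt, _ = _neighbourhood_pass(levels)
    usable = in_roi & (nbr_cnt > 0)
    diff = np.zeros(levels.shape, dtype=np.float64)
    diff[usable] = np.abs(levels[usable] - nbr_sum[usable] / nbr_cnt[usable])
    n_i = np.zeros(n_levels, dtype=np.float64)
    s_i = np.zeros(n_levels, dtype=np.float64)
    np.add.at(n_i, levels[usable] - 1, 1.0)
    np.add.at(s_i, levels[usable] - 1, diff[usable])
    return n_i, s_i


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: float = 0.0) -> np.ndarray:
    """Dependence matrix: rows level, cols dependence count + 1 (26-neighbourhood)."""
    if alpha == 0.0:
        in_roi, _, _, dep = _neighbourhood_pass(levels)
    else:
        in_roi = levels > 0
        dep = np.zeros(levels.shape, dtype=np.int64)
        for off in OFFSETS_26:
            sh = _shift(levels, off)
            dep += in_roi & (sh > 0) & (np.abs(sh - levels) <= alpha)
    g = levels[in_roi] - 1
    d = dep[in_roi]
    mat = np.zeros((n_levels, int(d.max()) + 1 if d.size else 1), dtype=np.float64)
    np.add.at(mat, (g, d), 1.0)
    return mat


# ---------------------------------------------------------------------------
# features from matrices


def _glcm_features(counts: np.ndarray) -> dict[str, float]:
    ng = counts.shape[0]
    total = counts.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix (ROI has no neighbouring voxel pairs)")
    p = counts / total
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.bincount((ii + jj).ravel() - 2, weights=p.ravel(), minlength=2 * ng - 1)
    k_diff = np.arange(0, ng)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=ng)

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hxy = ent(p.ravel())
    with np.errstate(divide="ignore", invalid="ignore"):
        pxy = np.outer(px, py)
        mask = (p > 0) & (pxy > 0)
        hxy1 = float(-(p[mask] * np.log2(pxy[mask])).sum())
        hxy2 = ent_joint = float(-(pxy[pxy > 0] * np.log2(pxy[pxy > 0])).sum())
    hx, hy = ent(px), ent(py)

    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 1.0  # single gray level: perfectly correlated by convention
    imc1 = float((hxy - hxy1) / max(hx, hy)) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    if ng > 1 and sd_x > 0:
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
        a = p / np.where(px > 0, px, np.inf)[:, None]
        b = p / np.where(py > 0, py, np.inf)[None, :]
        q = a @ b.T
        eigs = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eigs[-2]))) if len(eigs) > 1 else 1.0
    else:
        mcc = 1.0

    da = float((k_diff * p_diff).sum())
    off_diag = ii != jj
    inv_var = float((p[off_diag] / (ii[off_diag] - jj[off_diag]) ** 2).sum())

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float((((ii + jj) - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float((((ii + jj) - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float((((ii + jj) - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": float(mu_x),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(((i - mu_x) ** 2 * px).sum()),
    }


def _run_zone_features(mat: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature formulas (runs vs zones)."""
    nr = mat.sum()
    if nr == 0:
        raise ValueError("empty run/zone matrix")
    g = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    l = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    pg = mat.sum(axis=1)
    pl = mat.sum(axis=0)
    p = mat / nr
    mu_g = (g * pg / nr).sum()
    mu_l = (l * pl / nr).sum()

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    vals = {
        "GrayLevelNonUniformity": float((pg**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nr**2),
        "GrayLevelVariance": float((p * ((g[:, None] - mu_g) ** 2)).sum()),
        "RunEntropy": ent(p.ravel()),
        "RunLengthNonUniformity": float((pl**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pl**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "RunVariance": float((p * ((l[None, :] - mu_l) ** 2)).sum()),
        "ShortRunEmphasis": float((pl / l**2).sum() / nr),
        "LongRunEmphasis": float((pl * l**2).sum() / nr),
        "LowGrayLevelRunEmphasis": float((pg / g**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((pg * g**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((mat / (g[:, None] ** 2 * l[None, :] ** 2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((mat * g[:, None] ** 2 / l[None, :] ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((mat * l[None, :] ** 2 / g[:, None] ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((mat * g[:, None] ** 2 * l[None, :] ** 2).sum() / nr),
    }
    if kind == "glrlm":
        return {k: vals[k] for k in GLRLM_NAMES}
    rename = {
        "RunEntropy": "ZoneEntropy",
        "RunLengthNonUniformity": "SizeZoneNonUniformity",
        "RunLengthNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
        "RunPercentage": "ZonePercentage",
        "RunVariance": "ZoneVariance",
        "ShortRunEmphasis": "SmallAreaEmphasis",
        "LongRunEmphasis": "LargeAreaEmphasis",
        "LowGrayLevelRunEmphasis": "LowGrayLevelZoneEmphasis",
        "HighGrayLevelRunEmphasis": "HighGrayLevelZoneEmphasis",
        "ShortRunLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
        "ShortRunHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
        "LongRunHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
    }
    out = {rename.get(k, k): v for k, v in vals.items()}
    return {k: out[k] for k in GLSZM_NAMES}


def _ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    nv = n_i.sum()
    if nv == 0:
        raise ValueError("NGTDM: no voxels with a valid neighbourhood")
    present = n_i > 0
    p = n_i / nv
    i = np.arange(1, len(n_i) + 1, dtype=np.float64)
    ip, sp, pp = i[present], s_i[present], p[present]
    ngp = int(present.sum())

    coarse_den = float((pp * sp).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        pij = pp[:, None] * pp[None, :]
        contrast = float((pij * di**2).sum()) * sp.sum() / (ngp * (ngp - 1) * nv)
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = float((pp * sp).sum() / busy_den) if busy_den > 0 else 0.0
        psum = pp[:, None] + pp[None, :]
        complexity = float((np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / psum).sum()) / nv
        strength_num = float((psum * di**2).sum())
        s_total = float(sp.sum())
        strength = strength_num / s_total if s_total > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


def _gldm_features(mat: np.ndarray) -> dict[str, float]:
    nz = mat.sum()
    if nz == 0:
        raise ValueError("empty dependence matrix")
    g = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    d = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    pg = mat.sum(axis=1)
    pd_ = mat.sum(axis=0)
    p = mat / nz
    mu_g = (g * pg / nz).sum()
    mu_d = (d * pd_ / nz).sum()
    q = p.ravel()
    q = q[q > 0]
    return {
        "DependenceEntropy": float(-(q * np.log2(q)).sum()),
        "DependenceNonUniformity": float((pd_**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd_**2).sum() / nz**2),
        "DependenceVariance": float((p * ((d[None, :] - mu_d) ** 2)).sum()),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelVariance": float((p * ((g[:, None] - mu_g) ** 2)).sum()),
        "HighGrayLevelEmphasis": float((pg * g**2).sum() / nz),
        "LargeDependenceEmphasis": float((pd_ * d**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((mat * g[:, None] ** 2 * d[None, :] ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((mat * d[None, :] ** 2 / g[:, None] ** 2).sum() / nz),
        "LowGrayLevelEmphasis": float((pg / g**2).sum() / nz),
        "SmallDependenceEmphasis": float((pd_ / d**2).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((mat * g[:, None] ** 2 / d[None, :] ** 2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((mat / (g[:, None] ** 2 * d[None, :] ** 2)).sum() / nz),
    }


def texture_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """All 75 texture features of a discretized ROI (levels 1..Ng, 0 outside)."""
    if (levels > 0).sum() < 2:
        raise ValueError("texture features need at least 2 ROI voxels")
    n_voxels = int((levels > 0).sum())

    glcm_acc: dict[str, list[float]] = {n: [] for n in GLCM_NAMES}
    glrlm_acc: dict[str, list[float]] = {n: [] for n in GLRLM_NAMES}
    for direction in DIRECTIONS_13:
        counts = glcm_matrix(levels, n_levels, direction)
        if counts.sum() > 0:
            for k, v in _glcm_features(counts).items():
                glcm_acc[k].append(v)
        for k, v in _run_zone_features(glrlm_matrix(levels, n_levels, direction), n_voxels, "glrlm").items():
            glrlm_acc[k].append(v)

    out: dict[str, float] = {}
    for k in GLCM_NAMES:
        out[f"glcm__{k}"] = float(np.mean(glcm_acc[k])) if glcm_acc[k] else 0.0
    for k in GLRLM_NAMES:
        out[f"glrlm__{k}"] = float(np.mean(glrlm_acc[k]))
    for k, v in _run_zone_features(glszm_matrix(levels, n_levels), n_voxels, "glszm").items():
        out[f"glszm__{k}"] = v
    for k, v in _ngtdm_features(*ngtdm_matrix(levels, n_levels)).items():
        out[f"ngtdm__{k}"] = v
    for k, v in _gldm_features(gldm_matrix(levels, n_levels)).items():
        out[f"gldm__{k}"] = v
    return out
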