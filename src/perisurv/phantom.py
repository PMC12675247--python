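"""Synthetic CT-phantom cohorts with planted prognostic signal.

The generator produces thoracic-CT-like phantoms: a noisy lung-parenchyma
background (~ -800 HU), a single solid ellipsoidal tumor (~ +40 HU) carrying
subject-specific Gaussian texture, and a peritumoral intensity-gradient
shell of subject-specific width.  Right-censored survival is drawn from a
Weibull proportional-hazards model whose log-hazard depends on three
image-derived covariates: log tumor volume, intra-tumor texture contrast,
and rim width.  Everything needed to recover the planted signal (covariates,
linear predictors, true event times) is recorded.

All distributional choices here are synthetic stand-ins: the pipeline's
intended inputs are real planning-CT cohorts, which have no known generative
model.  See ``docs/methods.md`` for what the phantoms do and do not emulate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CTVolume

__all__ = [
    "PhantomSpec",
    "SimulationTruth",
    "Cohort",
    "generate_phantom",
    "simulate_survival",
    "generate_cohort",
    "subject_seeds",
]

#: required clearance (mm) between the largest allowed tumor and the volume edge
_FIT_MARGIN_MM = 10.0

#: names of the planted covariates, in the order of SimulationTruth.beta
COVARIATE_NAMES = ("log_tumor_volume", "texture_contrast", "rim_width")


@dataclass
class PhantomSpec:
    """Geometry and intensity model of a single-tumor CT phantom.

    Intensities are HU-like (lung parenchyma ~ -800, tumor ~ +40) so that
    normalization code paths behave as they would on real CT.
    """

    volume_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_mean: float = -800.0
    background_sd: float = 50.0
    tumor_radius_range_mm: tuple[float, float] = (5.0, 20.0)
    tumor_mean_intensity: float = 40.0
    texture_contrast_range: tuple[float, float] = (10.0, 60.0)
    rim_width_range_mm: tuple[float, float] = (2.0, 6.0)

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(n) for n in self.volume_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        for name in ("tumor_radius_range_mm", "texture_contrast_range", "rim_width_range_mm"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ValueError(f"{name} must be a nonempty (min, max) range, got {(lo, hi)}")
        if self.tumor_radius_range_mm[0] < 0 or self.rim_width_range_mm[0] < 0:
            raise ValueError("radius and rim width must be nonnegative")
        if self.background_sd < 0 or self.texture_contrast_range[0] < 0:
            raise ValueError("noise levels must be nonnegative")
        half_extent = min(n * s for n, s in zip(self.volume_shape, self.spacing_mm)) / 2.0
        if self.tumor_radius_range_mm[1] + _FIT_MARGIN_MM > half_extent:
            raise ValueError(
                f"largest tumor radius {self.tumor_radius_range_mm[1]} mm plus the "
                f"{_FIT_MARGIN_MM} mm margin does not fit in a volume of half-extent {half_extent} mm"
            )


@dataclass
class SimulationTruth:
    """Generative survival model: Weibull baseline under proportional hazards.

    ``beta`` multiplies the cohort-standardized covariates
    (log tumor volume, texture contrast, rim width).  Event time is
    ``T = scale * (E * exp(-eta))**(1/shape)`` with ``E ~ Exp(1)``;
    censoring is administrative, uniform on ``censoring_window_days`` and
    independent of the covariates.
    """

    beta: tuple[float, float, float] = (0.8, 0.5, 0.3)
    weibull_shape: float = 1.2
    weibull_scale_days: float = 700.0
    censoring_window_days: tuple[float, float] = (60.0, 1825.0)

    def __post_init__(self) -> None:
        self.beta = tuple(float(b) for b in self.beta)
        if len(self.beta) != len(COVARIATE_NAMES):
            raise ValueError(f"beta must have {len(COVARIATE_NAMES)} components")
        if self.weibull_shape <= 0 or self.weibull_scale_days <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        c_min, c_max = self.censoring_window_days
        if not (0 < c_min <= c_max):
            raise ValueError("censoring window must satisfy 0 < c_min <= c_max")


@dataclass
class Cohort:
    """An in-memory synthetic cohort plus its ground truth."""

    volumes: list[CTVolume]
    masks: list[CTVolume]
    table: pd.DataFrame  # subject_id, time_days, event, truth_* columns
    spec: PhantomSpec
    truth: SimulationTruth
    seed: int

    def __len__(self) -> int:
        return len(self.volumes)


def subject_seeds(master_seed: int, n: int) -> list[int]:
    """Derive per-subject seeds from a master seed.

    Splitting rule (fixed, documented in the README): the master seed feeds
    ``numpy.random.SeedSequence`` and each subject uses one spawned child.
    """
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(master_seed).spawn(n)]


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[CTVolume, CTVolume, dict[str, float]]:
    """Generate one phantom: CT volume, binary GTV mask, and its covariates.

    The tumor is a solid ellipsoid whose semi-axes are drawn independently
    from ``tumor_radius_range_mm``; tumor voxels carry the mean tumor
    intensity plus zero-mean Gaussian texture of a drawn subject-level SD;
    a shell of drawn width outside the mask interpolates linearly from the
    tumor intensity down to the noisy background.
    """
    rng = np.random.default_rng(seed)
    shape, spacing = spec.volume_shape, spec.spacing_mm

    semi_axes = rng.uniform(*spec.tumor_radius_range_mm, size=3)
    contrast = rng.uniform(*spec.texture_contrast_range)
    rim_width = rng.uniform(*spec.rim_width_range_mm)

    extent = np.array([n * s for n, s in zip(shape, spacing)])
    clearance = semi_axes + rim_width + 1.0
    lo, hi = clearance, extent - clearance
    if np.any(lo >= hi):
        raise ValueError(
            f"tumor with semi-axes {np.round(semi_axes, 2)} mm plus rim {rim_width:.2f} mm "
            f"does not fit inside the volume extent {extent} mm"
        )
    center = rng.uniform(lo, hi)

    coords = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij")
    r2 = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semi_axes))
    mask = r2 <= 1.0
    if not mask.any():
        raise ValueError("drawn tumor contains no voxels; radius range too small for the grid")
    n_comp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))[1]
    if n_comp != 1:
        raise ValueError(f"tumor mask is not a single 6-connected component ({n_comp} parts)")

    data = rng.normal(spec.background_mean, spec.background_sd, size=shape)
    data[mask] = spec.tumor_mean_intensity + rng.normal(0.0, 1.0, size=int(mask.sum())) * contrast

    if rim_width > 0:
        dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
        shell = (dist > 0) & (dist <= rim_width)
        w = dist[shell] / rim_width  # 0 at the tumor border, 1 at the outer edge
        data[shell] = (1.0 - w) * spec.tumor_mean_intensity + w * data[shell]

    voxel_vol = float(np.prod(spacing))
    covariates = {
        "log_tumor_volume": float(np.log(mask.sum() * voxel_vol)),
        "texture_contrast": float(contrast),
        "rim_width": float(rim_width),
    }
    vol = CTVolume(data.astype(np.float32), spacing)
    gtv = CTVolume(mask.astype(np.uint8), spacing)
    return vol, gtv, covariates


def simulate_survival(
    covariates: pd.DataFrame, truth: SimulationTruth, seed: int
) -> pd.DataFrame:
    """Draw right-censored survival from the Weibull proportional-hazards model.

    Covariates are standardized with cohort statistics before entering the
    linear predictor, so ``beta`` is on a per-SD scale.  Returns a frame
    with observed ``time_days``, ``event`` and the truth columns
    (``truth_eta``, ``truth_event_time``, ``truth_censor_time``).
    """
    x = covariates.loc[:, list(COVARIATE_NAMES)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    eta = z @ np.asarray(truth.beta)

    e = rng.exponential(size=len(x))
    t_event = truth.weibull_scale_days * (e * np.exp(-eta)) ** (1.0 / truth.weibull_shape)
    c_min, c_max = truth.censoring_window_days
    t_cens = rng.uniform(c_min, c_max, size=len(x))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if np.any(time <= 0):  # pragma: no cover - Weibull draws are strictly positive
        raise RuntimeError("nonpositive simulated time")

    return pd.DataFrame(
        {
            "time_days": time,
            "event": event,
            "truth_eta": eta,
            "truth_event_time": t_event,
            "truth_censor_time": t_cens,
        },
        index=covariates.index,
    )


def generate_cohort(
    n: int,
    spec: PhantomSpec | None = None,
    truth: SimulationTruth | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate a full synthetic cohort (volumes, masks, survival table, truth).

    Per-subject seeds are derived deterministically from the master seed
    (see :func:`subject_seeds`); identical arguments reproduce the cohort
    bit-identically.  With ``out_dir`` the volumes/masks are written as
    NIfTI pairs and the survival table as CSV.
    """
    if n < 2:
        raise ValueError("a cohort needs n >= 2 subjects")
    spec = spec or PhantomSpec()
    truth = truth or SimulationTruth()

    seeds = subject_seeds(seed, n + 1)
    volumes, masks, rows = [], [], []
    for i in range(n):
        vol, gtv, cov = generate_phantom(spec, seeds[i])
        volumes.append(vol)
        masks.append(gtv)
        rows.append(cov)
    ids = [f"S{i:04d}" for i in range(n)]
    cov_df = pd.DataFrame(rows, index=ids)
    surv = simulate_survival(cov_df, truth, seeds[n])

    table = pd.DataFrame({"subject_id": ids})
    table["time_days"] = surv["time_days"].to_numpy()
    table["event"] = surv["event"].to_numpy()
    for c in COVARIATE_NAMES:
        table[f"truth_{c}"] = cov_df[c].to_numpy()
    for c in ("truth_eta", "truth_event_time", "truth_censor_time"):
        table[c] = surv[c].to_numpy()

    cohort = Cohort(volumes, masks, table, spec, truth, seed)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, vol, gtv in zip(cohort.table["subject_id"], cohort.volumes, cohort.masks):
        vol.to_nifti(out / f"{sid}_ct.nii.gz")
        gtv.to_nifti(out / f"{sid}_gtv.nii.gz")
    cohort.table.to_csv(out / "survival.csv", index=False, float_format="%.10g")
    return out
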