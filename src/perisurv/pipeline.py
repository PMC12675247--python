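"""End-to-end orchestration: simulate -> preprocess -> rings -> radiomics ->
deep survival -> selection/fusion -> evaluation, reproducibly from one config.

A run directory accumulates one subdirectory per stage; expensive stages
(cohort synthesis, preprocessing, ring construction, radiomics, network
training) are cached by config hash and skipped when already computed with
an identical configuration, while the cheap modelling/evaluation stages are
recomputed (they are deterministic given their inputs).  A manifest records
the package version, the config hash, the seeds, and the content hash of
every artifact; two runs of the same config produce identical manifests.

The train/test split mimics a two-centre design: the cohorts are generated
from disjoint master seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import evaluate_risk_score, calibration_curve, harrell_cindex, bootstrap_ci
from .fusion import FusionConfig, RiskFusionModel
from .nn import ArchitectureConfig
from .phantom import PhantomSpec, SimulationTruth, generate_cohort, write_cohort
from .preprocess import crop_resize_roi, resample_isotropic, resample_mask
from .radiomics import DiscretizationParams, FilterBank, extract_all
from .roi import build_roi_set
from .selection import SelectionConfig, lasso_cox_select, univariate_cox_filter, zscore_fit_apply
from .survival_net import DeepSurvivalModel, TrainingConfig

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "compare_expansion_distances"]

SCHEMA_VERSION = 1

_CONFIG_KEYS = {
    "out_dir", "preset", "seed", "n_train", "n_test", "distances", "horizons",
    "fusion_distance_mm", "block_size", "phantom", "truth", "dl", "selection",
    "variance_threshold", "n_bootstrap", "schema_version",
}


@dataclass
class PipelineConfig:
    """One config to govern every stage; schema-validated before any compute."""

    out_dir: str = "perisurv_run"
    preset: str = "desk"  # "desk" (CPU-scale) or "full"
    seed: int = 0
    n_train: int = 40
    n_test: int = 20
    distances: tuple[float, ...] = (3.0, 6.0, 9.0)
    horizons: tuple[float, ...] = (365.0, 730.0, 1095.0)
    fusion_distance_mm: float = 6.0  # the peritumoral block entering the combined model
    block_size: int | None = None  # derived from preset when None
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    truth: dict = field(default_factory=dict)  # SimulationTruth overrides
    dl: dict = field(default_factory=dict)  # TrainingConfig overrides
    selection: dict = field(default_factory=dict)  # SelectionConfig overrides
    variance_threshold: float = 0.95
    n_bootstrap: int = 200
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.preset not in ("desk", "full"):
            raise ValueError("preset must be 'desk' or 'full'")
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {self.schema_version}")
        if self.n_train < 2 or self.n_test < 2:
            raise ValueError("cohorts need n >= 2")
        if self.fusion_distance_mm not in self.distances:
            raise ValueError("fusion_distance_mm must be one of the expansion distances")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("distances", "horizons"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    # -- derived objects ----------------------------------------------------

    def phantom_spec(self) -> PhantomSpec:
        if self.preset == "desk":
            base = dict(volume_shape=(72, 72, 72), tumor_radius_range_mm=(5.0, 14.0))
        else:
            base = {}
        base.update(self.phantom)
        return PhantomSpec(**base)

    def simulation_truth(self) -> SimulationTruth:
        return SimulationTruth(**self.truth)

    def effective_block_size(self) -> int:
        return self.block_size or (32 if self.preset == "desk" else 64)

    def arch_config(self) -> ArchitectureConfig:
        if self.preset == "desk":
            return ArchitectureConfig.desk(input_size=self.effective_block_size())
        return ArchitectureConfig(input_size=self.effective_block_size())

    def training_config(self) -> TrainingConfig:
        kw = dict(self.dl)
        kw.setdefault("seed", self.seed)
        if self.preset == "desk":
            return TrainingConfig.desk(**kw)
        return TrainingConfig(**kw)

    def selection_config(self) -> SelectionConfig:
        kw = dict(self.selection)
        kw.setdefault("seed", self.seed)
        return SelectionConfig(**kw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # location does not affect the science
        payload["version"] = __version__
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage plumbing


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_dir(run_dir: Path, name: str) -> Path:
    d = run_dir / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _stage_done(stage: Path, config_hash: str) -> bool:
    mf = stage / "stage_manifest.json"
    if not mf.exists():
        return False
    try:
        return json.loads(mf.read_text()).get("config_hash") == config_hash
    except json.JSONDecodeError:
        return False


def _finish_stage(stage: Path, config_hash: str) -> dict:
    files = {
        str(p.relative_to(stage)): _hash_file(p)
        for p in sorted(stage.rglob("*"))
        if p.is_file() and p.name != "stage_manifest.json"
    }
    manifest = {"config_hash": config_hash, "files": files}
    (stage / "stage_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stages


def _cohort_seeds(seed: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(seed).spawn(2)
    return int(ss[0].generate_state(1)[0] % 2**31), int(ss[1].generate_state(1)[0] % 2**31)


def stage_simulate(cfg: PipelineConfig, run_dir: Path) -> dict:
    stage = _stage_dir(run_dir, "simulate")
    ch = cfg.config_hash()
    spec, truth = cfg.phantom_spec(), cfg.simulation_truth()
    seed_train, seed_test = _cohort_seeds(cfg.seed)
    cohorts = {}
    for split, n, seed in (("train", cfg.n_train, seed_train), ("test", cfg.n_test, seed_test)):
        out = stage / split
        if not (_stage_done(stage, ch) and (out / "survival.csv").exists()):
            cohort = generate_cohort(n, spec, truth, seed=seed, out_dir=out)
        else:
            cohort = None
        cohorts[split] = (out, n, seed)
    if not _stage_done(stage, ch):
        _finish_stage(stage, ch)
    return {"dirs": cohorts, "spec": spec, "truth": truth}


def _load_cohort_tables(sim: dict) -> dict[str, pd.DataFrame]:
    out = {}
    for split, (d, _, _) in sim["dirs"].items():
        out[split] = pd.read_csv(d / "survival.csv").set_index("subject_id")
    return out


def stage_preprocess(cfg: PipelineConfig, run_dir: Path, sim: dict) -> dict:
    """Isotropic resampling + network-input blocks for every subject."""
    from .core import CTVolume

    stage = _stage_dir(run_dir, "preprocess")
    ch = cfg.config_hash()
    bs = cfg.effective_block_size()
    blocks = {}
    for split, (d, n, _) in sim["dirs"].items():
        path = stage / f"blocks_{split}.npy"
        ids = pd.read_csv(d / "survival.csv")["subject_id"].tolist()
        if _stage_done(stage, ch) and path.exists():
            blocks[split] = np.load(path)
            continue
        arrs = []
        for sid in ids:
            vol = resample_isotropic(CTVolume.from_nifti(d / f"{sid}_ct.nii.gz"))
            mask = resample_mask(CTVolume.from_nifti(d / f"{sid}_gtv.nii.gz"))
            arrs.append(crop_resize_roi(vol, mask, block_size=bs, subject_id=sid).data)
        blocks[split] = np.stack(arrs).astype(np.float32)
        np.save(path, blocks[split])
    if not _stage_done(stage, ch):
        _finish_stage(stage, ch)
    return blocks


def stage_radiomics(cfg: PipelineConfig, run_dir: Path, sim: dict) -> dict:
    """Rings + 1316 features per region per subject (rings cached as NIfTI)."""
    from .core import CTVolume

    ring_stage = _stage_dir(run_dir, "rings")
    feat_stage = _stage_dir(run_dir, "radiomics")
    ch = cfg.config_hash()
    params = DiscretizationParams()
    bank = FilterBank()
    tables = {}
    for split, (d, n, _) in sim["dirs"].items():
        path = feat_stage / f"features_{split}.csv"
        if _stage_done(feat_stage, ch) and path.exists():
            tables[split] = pd.read_csv(path, index_col=[0, 1])
            continue
        ids = pd.read_csv(d / "survival.csv")["subject_id"].tolist()
        rows = []
        t0 = time.time()
        for sid in ids:
            vol = resample_isotropic(CTVolume.from_nifti(d / f"{sid}_ct.nii.gz"))
            mask = resample_mask(CTVolume.from_nifti(d / f"{sid}_gtv.nii.gz"))
            rois = build_roi_set(mask, distances=cfg.distances)
            for dist in cfg.distances:
                out = ring_stage / split / f"{sid}_ring{dist:g}mm.nii.gz"
                if not out.exists():
                    out.parent.mkdir(parents=True, exist_ok=True)
                    CTVolume(rois.rings[float(dist)].astype(np.uint8), mask.spacing).to_nifti(out)
            feats = extract_all(vol, rois, params, bank)
            feats.index = pd.MultiIndex.from_product([[sid], feats.index], names=["subject_id", "region"])
            rows.append(feats)
        pd.concat(rows).to_csv(path, float_format="%.10g")
        # read back so fresh and cached runs feed bit-identical tables downstream
        tables[split] = pd.read_csv(path, index_col=[0, 1])
        log.info("radiomics %s: %d subjects in %.1f s", split, len(ids), time.time() - t0)
    if not _stage_done(ring_stage, ch):
        _finish_stage(ring_stage, ch)
    if not _stage_done(feat_stage, ch):
        _finish_stage(feat_stage, ch)
    return tables


def stage_train_dl(cfg: PipelineConfig, run_dir: Path, sim: dict, blocks: dict) -> dict:
    """Train the survival network; export GAP features for both splits."""
    stage = _stage_dir(run_dir, "dl")
    ch = cfg.config_hash()
    tabs = _load_cohort_tables(sim)
    feats = {}
    if _stage_done(stage, ch) and all((stage / f"gap_{s}.csv").exists() for s in blocks):
        for split in blocks:
            feats[split] = pd.read_csv(stage / f"gap_{split}.csv", index_col=0)
        history = pd.read_csv(stage / "history.csv")
        return {"gap": feats, "history": history}

    surv = tabs["train"]
    model = DeepSurvivalModel(
        blocks["train"], surv["time_days"].to_numpy(), surv["event"].to_numpy(),
        arch=cfg.arch_config(), training=cfg.training_config(),
    )
    res = model.fit()
    res.history.to_csv(stage / "history.csv", index=False, float_format="%.8g")
    np.savez(stage / "checkpoint.npz", **res.network.state_dict())
    for split, arr in blocks.items():
        gap = res.extract_gap_features(arr)
        df = pd.DataFrame(gap, index=tabs[split].index,
                          columns=[f"deep_{i:03d}" for i in range(gap.shape[1])])
        df.to_csv(stage / f"gap_{split}.csv", float_format="%.8g")
        # reload so fresh and cached runs feed identical values downstream
        feats[split] = pd.read_csv(stage / f"gap_{split}.csv", index_col=0)
    (stage / "summary.txt").write_text(res.summary() + "\n")
    _finish_stage(stage, ch)
    return {"gap": feats, "history": res.history}


def _region_blocks(features: pd.DataFrame, fusion_distance: float) -> dict[str, pd.DataFrame]:
    intra = features.xs("intratumoral", level="region")
    peri = features.xs(f"peri{fusion_distance:g}mm", level="region")
    return {"rad_intra": intra, f"rad_peri{fusion_distance:g}": peri}


def stage_select_fuse(cfg: PipelineConfig, run_dir: Path, sim: dict,
                      radiomics: dict, dl: dict):
    """Fit the combined risk model on the training cohort."""
    stage = _stage_dir(run_dir, "model")
    tabs = _load_cohort_tables(sim)
    blocks = _region_blocks(radiomics["train"], cfg.fusion_distance_mm)
    blocks["deep"] = dl["gap"]["train"]
    fusion_cfg = FusionConfig(selection=cfg.selection_config(),
                              variance_threshold=cfg.variance_threshold)
    surv = tabs["train"][["time_days", "event"]]
    model = RiskFusionModel(blocks, surv, fusion_cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    res.to_json(stage / "model.json")
    (stage / "summary.txt").write_text(res.summary() + "\n")
    res.pca.loadings_frame().to_csv(stage / "pca_loadings.csv", float_format="%.8g")
    _finish_stage(stage, cfg.config_hash())
    return res


def stage_evaluate(cfg: PipelineConfig, run_dir: Path, sim: dict,
                   radiomics: dict, dl: dict, model) -> dict:
    """Discrimination/calibration/stratification reports plus figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stage = _stage_dir(run_dir, "evaluation")
    tabs = _load_cohort_tables(sim)
    reports = {}
    for split in ("train", "test"):
        blocks = _region_blocks(radiomics[split], cfg.fusion_distance_mm)
        blocks["deep"] = dl["gap"][split]
        surv = tabs[split]
        t = surv["time_days"].to_numpy()
        e = surv["event"].to_numpy()
        risk = model.predict_risk(blocks)
        groups = (risk > model.cutoff).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = evaluate_risk_score(risk, t, e, horizons=cfg.horizons,
                                      risk_groups=groups, n_boot=cfg.n_bootstrap,
                                      seed=cfg.seed)
        reports[split] = rep
        payload = rep.to_dict()
        (stage / f"report_{split}.json").write_text(json.dumps(payload, indent=1))
        pd.DataFrame({"subject_id": surv.index, "risk": risk, "group": groups}).to_csv(
            stage / f"risk_{split}.csv", index=False, float_format="%.8g"
        )

        # KM figure per risk group
        fig, ax = plt.subplots(figsize=(5, 4))
        for gname, tab in (rep.km or {}).items():
            ax.step(tab["time"], tab["survival"], where="post",
                    label=f"{'high' if gname == '1' else 'low'} risk")
        ax.set_xlabel("days")
        ax.set_ylabel("survival probability")
        ax.set_title(f"KM by median-risk group ({split})")
        ax.legend()
        fig.savefig(stage / f"km_{split}.png", dpi=100)
        plt.close(fig)

        # calibration at the middle horizon
        h = cfg.horizons[len(cfg.horizons) // 2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = model.predict_survival_at(blocks, h)
            cal = calibration_curve(pred, t, e, horizon=h, n_boot=cfg.n_bootstrap,
                                    seed=cfg.seed)
        cal.to_csv(stage / f"calibration_{split}.csv", index=False, float_format="%.8g")
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.errorbar(cal["predicted"], cal["observed"],
                    yerr=[cal["observed"] - cal["observed_lo"],
                          cal["observed_hi"] - cal["observed"]], fmt="o-")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel(f"predicted S({h:g} d)")
        ax.set_ylabel("observed (KM)")
        fig.savefig(stage / f"calibration_{split}.png", dpi=100)
        plt.close(fig)

        # time-dependent AUC bar figure
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        hs = sorted(rep.auc)
        ax.bar([f"{int(h / 365)}y" for h in hs], [rep.auc[h] for h in hs])
        ax.set_ylim(0, 1)
        ax.set_ylabel("time-dependent AUC")
        ax.set_title(f"combined model ({split})")
        fig.savefig(stage / f"auc_{split}.png", dpi=100)
        plt.close(fig)
    _finish_stage(stage, cfg.config_hash())
    return reports


def compare_expansion_distances(cfg: PipelineConfig, run_dir: Path, sim: dict,
                                radiomics: dict) -> pd.DataFrame:
    """Per-scheme signature C-indices: Rad, Rad_d, and Rad+Rad_d for each d."""
    stage = _stage_dir(run_dir, "distance_comparison")
    tabs = _load_cohort_tables(sim)
    t_tr = tabs["train"]["time_days"].to_numpy()
    e_tr = tabs["train"]["event"].to_numpy()
    t_te = tabs["test"]["time_days"].to_numpy()
    e_te = tabs["test"]["event"].to_numpy()

    def region_table(split, region):
        return radiomics[split].xs(region, level="region").add_prefix(f"{region}:")

    schemes: dict[str, list[str]] = {"Rad": ["intratumoral"]}
    for d in cfg.distances:
        schemes[f"Rad_{d:g}mm"] = [f"peri{d:g}mm"]
    for d in cfg.distances:
        schemes[f"Rad+Rad_{d:g}mm"] = ["intratumoral", f"peri{d:g}mm"]

    sel_cfg = cfg.selection_config()
    rows = []
    rng_seed = cfg.seed
    for name, regions in schemes.items():
        train = pd.concat([region_table("train", r) for r in regions], axis=1)
        test = pd.concat([region_table("test", r) for r in regions], axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z, stats_df = zscore_fit_apply(train)
            screen = univariate_cox_filter(z, t_tr, e_tr, alpha=sel_cfg.alpha)
            kept = screen.index[screen["kept"]]
            if len(kept) == 0:
                rows.append({"signature": name, "n_screened": 0, "n_selected": 0,
                             "cindex_train": np.nan, "cindex_test": np.nan})
                continue
            sig = lasso_cox_select(z[kept], t_tr, e_tr, sel_cfg, stats_df=stats_df.loc[kept])
        from .selection import signature_score

        def scheme_row(sig=sig, train=train, test=test, name=name, kept=kept):
            s_tr = signature_score(sig, train)
            s_te = signature_score(sig, test)
            c_tr = harrell_cindex(s_tr, t_tr, e_tr) if len(sig) else np.nan
            c_te = harrell_cindex(s_te, t_te, e_te) if len(sig) else np.nan
            ci_tr = bootstrap_ci(lambda i: harrell_cindex(s_tr[i], t_tr[i], e_tr[i]),
                                 len(s_tr), cfg.n_bootstrap, rng_seed) if len(sig) else (np.nan, np.nan)
            ci_te = bootstrap_ci(lambda i: harrell_cindex(s_te[i], t_te[i], e_te[i]),
                                 len(s_te), cfg.n_bootstrap, rng_seed) if len(sig) else (np.nan, np.nan)
            return {
                "signature": name, "n_screened": int(screen["kept"].sum()),
                "n_selected": len(sig),
                "cindex_train": c_tr, "cindex_train_lo": ci_tr[0], "cindex_train_hi": ci_tr[1],
                "cindex_test": c_te, "cindex_test_lo": ci_te[0], "cindex_test_hi": ci_te[1],
            }

        rows.append(scheme_row())
    table = pd.DataFrame(rows)
    table.to_csv(stage / "cindex_by_distance.csv", index=False, float_format="%.6g")
    _finish_stage(stage, cfg.config_hash())
    return table


# ---------------------------------------------------------------------------
# the full run


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = (
    "simulate", "preprocess", "rings", "radiomics", "dl", "select", "evaluate", "compare",
)) -> dict:
    """Execute the pipeline; returns stage outputs and writes manifest.json."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    state: dict = {"run_dir": run_dir}
    t0 = time.time()

    sim = stage_simulate(cfg, run_dir)
    state["sim"] = sim
    log.info("simulate done (%.1f s)", time.time() - t0)
    if "preprocess" in stages or "dl" in stages:
        state["blocks"] = stage_preprocess(cfg, run_dir, sim)
        log.info("preprocess done (%.1f s)", time.time() - t0)
    if "radiomics" in stages or "rings" in stages:
        state["radiomics"] = stage_radiomics(cfg, run_dir, sim)
        log.info("radiomics done (%.1f s)", time.time() - t0)
    if "dl" in stages:
        state["dl"] = stage_train_dl(cfg, run_dir, sim, state["blocks"])
        log.info("deep survival done (%.1f s)", time.time() - t0)
    if "select" in stages:
        state["model"] = stage_select_fuse(cfg, run_dir, sim, state["radiomics"], state["dl"])
        log.info("selection/fusion done (%.1f s)", time.time() - t0)
    if "evaluate" in stages:
        state["reports"] = stage_evaluate(cfg, run_dir, sim, state["radiomics"],
                                          state["dl"], state["model"])
        log.info("evaluation done (%.1f s)", time.time() - t0)
    if "compare" in stages:
        state["distance_table"] = compare_expansion_distances(cfg, run_dir, sim,
                                                              state["radiomics"])
        log.info("distance comparison done (%.1f s)", time.time() - t0)

    # aggregate manifest (deterministic: no timestamps)
    manifest = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    for stage_name in ("simulate", "preprocess", "rings", "radiomics", "dl",
                       "model", "evaluation", "distance_comparison"):
        mf = run_dir / stage_name / "stage_manifest.json"
        if mf.exists():
            manifest["stages"][stage_name] = json.loads(mf.read_text())
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    state["manifest"] = manifest
    return state
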