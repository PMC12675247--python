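"""PCA fusion of selected feature blocks and the combined Cox risk model.

The fitted object follows the statsmodels convention: build a
:class:`RiskFusionModel` from per-block feature tables plus survival, call
``fit()`` and receive a :class:`RiskModelResults` carrying the selected
signatures, PCA loadings, Cox coefficients with their uncertainty, the
training-median stratification cutoff, and ``summary()``.

Per block (e.g. intratumoral radiomics, 6 mm peritumoral radiomics, deep
features) the chain is: training-statistics z-score -> univariate Cox
screen -> Lasso-Cox -> signature.  The default fusion performs PCA on the
selected raw (standardized) features of all blocks concatenated, keeping
the smallest component count reaching 95 % cumulative explained variance,
and fits a multivariable Cox model on the retained components.  A config
switch fuses per-block signature scores instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.decomposition import PCA

from .selection import (
    SelectionConfig,
    Signature,
    apply_zscore,
    lasso_cox_select,
    signature_score,
    univariate_cox_filter,
    zscore_fit_apply,
)

__all__ = ["FusionConfig", "PCAFusion", "RiskFusionModel", "RiskModelResults", "pca_fuse"]


@dataclass
class FusionConfig:
    """Selection + fusion settings for the combined model."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    variance_threshold: float = 0.95
    fuse_on: str = "selected_features"  # or "signature_scores"
    max_pca_features: int = 500  # warn-only cap

    def __post_init__(self) -> None:
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance threshold must be in (0, 1]")
        if self.fuse_on not in ("selected_features", "signature_scores"):
            raise ValueError("fuse_on must be 'selected_features' or 'signature_scores'")


@dataclass
class PCAFusion:
    """Fitted PCA with the retained-component rule."""

    mean: np.ndarray
    components: np.ndarray  # (k, p) loadings
    explained_ratio: np.ndarray
    feature_names: list[str]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) @ self.components.T

    def loadings_frame(self) -> pd.DataFrame:
        idx = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.components, index=idx, columns=self.feature_names)


def pca_fuse(x: np.ndarray, feature_names, threshold: float = 0.95,
             max_features: int = 500) -> PCAFusion:
    """PCA on training rows; keep the smallest k reaching the variance threshold."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] > max_features:
        warnings.warn(f"PCA over {x.shape[1]} features exceeds the documented cap {max_features}")
    pca = PCA(svd_solver="full")
    pca.fit(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, len(cum))
    return PCAFusion(
        mean=pca.mean_,
        components=pca.components_[:k],
        explained_ratio=pca.explained_variance_ratio_[:k],
        feature_names=list(feature_names),
    )


@dataclass
class RiskModelResults:
    """Fitted selection + PCA + Cox scoring chain."""

    signatures: dict[str, Signature]
    screening: dict[str, pd.DataFrame]
    pca: PCAFusion
    cox: CoxPHFitter
    cutoff: float
    config: FusionConfig
    train_index: pd.Index
    train_risk: pd.Series

    # -- scoring ------------------------------------------------------------

    def _fused_matrix(self, blocks: dict[str, pd.DataFrame]) -> np.ndarray:
        cols = []
        if self.config.fuse_on == "selected_features":
            for name, sig in self.signatures.items():
                if len(sig) == 0:
                    continue
                z = apply_zscore(blocks[name], sig.stats)
                cols.append(z.to_numpy())
        else:
            for name, sig in self.signatures.items():
                cols.append(signature_score(sig, blocks[name])[:, None])
        return np.hstack(cols)

    def predict_risk(self, blocks: dict[str, pd.DataFrame]) -> np.ndarray:
        """Linear predictor of the combined Cox model."""
        comps = self.pca.transform(self._fused_matrix(blocks))
        beta = self.cox.params_.to_numpy()
        return comps @ beta

    def risk_groups(self, blocks: dict[str, pd.DataFrame]) -> np.ndarray:
        """0 = low risk, 1 = high risk by the training-median cutoff."""
        return (self.predict_risk(blocks) > self.cutoff).astype(int)

    def predict_survival_at(self, blocks: dict[str, pd.DataFrame], horizon: float) -> np.ndarray:
        """Model-based survival probability at a horizon (Breslow baseline)."""
        comps = self.pca.transform(self._fused_matrix(blocks))
        df = pd.DataFrame(comps, columns=self.cox.params_.index)
        sf = self.cox.predict_survival_function(df, times=[horizon])
        return sf.iloc[0].to_numpy()

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = ["Combined peritumoral/deep-feature risk model", "=" * 46]
        for name, sig in self.signatures.items():
            screened = int(self.screening[name]["kept"].sum())
            lines.append(f"  block {name:<24} screened {screened:>4}  selected {len(sig):>3}")
        lines.append(
            f"  PCA: {self.pca.n_components} components "
            f"({self.pca.explained_ratio.sum():.1%} of variance, threshold "
            f"{self.config.variance_threshold:.0%})"
        )
        lines.append(f"  stratification cutoff (training median risk): {self.cutoff:.4f}")
        lines.append("")
        with pd.option_context("display.width", 100):
            lines.append(str(self.cox.summary[["coef", "se(coef)", "p"]]))
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "perisurv-risk-model",
            "version": 1,
            "fuse_on": self.config.fuse_on,
            "variance_threshold": self.config.variance_threshold,
            "signatures": {k: v.to_dict() for k, v in self.signatures.items()},
            "pca": {
                "mean": self.pca.mean.tolist(),
                "components": self.pca.components.tolist(),
                "explained_ratio": self.pca.explained_ratio.tolist(),
                "feature_names": self.pca.feature_names,
            },
            "cox_coef": self.cox.params_.to_list(),
            "cutoff": self.cutoff,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


class RiskFusionModel:
    """Build the combined risk model from per-block feature tables.

    Parameters
    ----------
    feature_blocks : dict of DataFrame
        Per-block subjects x features tables on a shared index
        (e.g. ``{"rad_intra": ..., "rad_peri6": ..., "deep": ...}``).
    survival : DataFrame
        Must carry ``time_days`` and ``event`` on the same index.
    """

    def __init__(self, feature_blocks: dict[str, pd.DataFrame], survival: pd.DataFrame,
                 config: FusionConfig | None = None):
        if not feature_blocks:
            raise ValueError("at least one feature block is required")
        idx = survival.index
        for name, tab in feature_blocks.items():
            if not tab.index.equals(idx):
                raise ValueError(f"block {name!r} is not aligned with the survival table")
        if int(survival["event"].sum()) < 2:
            raise ValueError("fitting needs >= 2 events")
        self.blocks = feature_blocks
        self.survival = survival
        self.config = config or FusionConfig()

    def fit(self) -> RiskModelResults:
        cfg = self.config
        t = self.survival["time_days"].to_numpy(dtype=float)
        d = self.survival["event"].to_numpy(dtype=int)

        signatures: dict[str, Signature] = {}
        screening: dict[str, pd.DataFrame] = {}
        for name, tab in self.blocks.items():
            z, stats_df = zscore_fit_apply(tab)
            screen = univariate_cox_filter(z, t, d, alpha=cfg.selection.alpha)
            screening[name] = screen
            kept = screen.index[screen["kept"]]
            if len(kept) == 0:
                warnings.warn(f"block {name!r}: no features survive univariate screening")
                signatures[name] = Signature([], np.array([]), stats_df.iloc[:0])
                continue
            signatures[name] = lasso_cox_select(
                z[kept], t, d, cfg.selection, stats_df=stats_df.loc[kept]
            )

        # fused design matrix on training rows
        cols, names = [], []
        if cfg.fuse_on == "selected_features":
            for name, sig in signatures.items():
                if len(sig) == 0:
                    continue
                cols.append(apply_zscore(self.blocks[name], sig.stats).to_numpy())
                names += [f"{name}:{f}" for f in sig.names]
        else:
            for name, sig in signatures.items():
                cols.append(signature_score(sig, self.blocks[name])[:, None])
                names.append(f"{name}:signature")
        if not cols:
            raise ValueError("no block selected any feature; cannot fuse")
        fused = np.hstack(cols)

        pca = pca_fuse(fused, names, cfg.variance_threshold, cfg.max_pca_features)
        comps = pca.transform(fused)
        comp_names = [f"PC{i + 1}" for i in range(comps.shape[1])]
        df = pd.DataFrame(comps, columns=comp_names, index=self.survival.index)
        df["time_days"] = t
        df["event"] = d
        cox = CoxPHFitter()
        try:
            cox.fit(df, "time_days", "event")
        except Exception as err:  # singular/collinear designs
            raise ValueError(f"combined Cox fit failed (singular design?): {err}") from err

        risk = pd.Series(comps @ cox.params_.to_numpy(), index=self.survival.index)
        cutoff = float(np.median(risk))
        return RiskModelResults(
            signatures=signatures,
            screening=screening,
            pca=pca,
            cox=cox,
            cutoff=cutoff,
            config=cfg,
            train_index=self.survival.index,
            train_risk=risk,
        )
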