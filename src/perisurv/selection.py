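"""Feature standardization, univariate Cox screening, and Lasso-Cox selection.

The screening stage fits one single-covariate Cox model per feature by
Newton-Raphson on the Breslow partial likelihood (vectorized across the
whole feature table, since tables here have ~1300 columns per region) and
keeps features with Wald p below the threshold.  The Lasso stage runs an
L1-penalized Cox path (scikit-survival's coxnet) with the penalty chosen
by 10-fold cross-validated Verweij-van Houwelingen partial-likelihood
deviance; the surviving nonzero-coefficient features form a Signature whose
score is a linear combination of stored-statistics-standardized features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "SelectionConfig",
    "Signature",
    "zscore_fit_apply",
    "univariate_cox_filter",
    "lasso_cox_select",
    "signature_score",
    "breslow_loglik",
]


@dataclass
class SelectionConfig:
    """Screening and Lasso-Cox settings."""

    alpha: float = 0.05
    cv_folds: int = 10
    n_penalties: int = 100
    penalty_min_ratio: float = 1e-4
    penalty_rule: str = "1se"  # "1se" (sparser, glmnet lambda.1se) or "min"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cross-validation needs >= 2 folds")


# ---------------------------------------------------------------------------
# standardization


def zscore_fit_apply(table: pd.DataFrame, train_ids=None):
    """Z-score a feature table with training-rows-only statistics.

    Returns ``(standardized table, stats)`` where ``stats`` is a frame with
    per-feature ``mean``/``sd`` (population SD).  Zero-SD columns are
    dropped with a warning.  Test rows (not in ``train_ids``) are
    transformed with the training statistics.
    """
    train = table if train_ids is None else table.loc[train_ids]
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    dead = sd[sd == 0].index
    if len(dead):
        warnings.warn(f"dropping {len(dead)} zero-variance feature(s)")
    keep = sd.index.difference(dead, sort=False)
    z = (table[keep] - mean[keep]) / sd[keep]
    stats_df = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    return z, stats_df


def apply_zscore(table: pd.DataFrame, stats_df: pd.DataFrame) -> pd.DataFrame:
    cols = stats_df.index
    missing = cols.difference(table.columns)
    if len(missing):
        raise KeyError(f"missing features: {list(missing[:5])}")
    return (table[cols] - stats_df["mean"]) / stats_df["sd"]


# ---------------------------------------------------------------------------
# Breslow partial likelihood (shared by screening and CV deviance)


def breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Log Breslow partial likelihood of linear predictors eta."""
    order = np.argsort(-time, kind="stable")
    e = eta[order]
    t = time[order]
    d = event[order]
    m = e.max() if len(e) else 0.0
    cum = np.logaddexp.accumulate(e - m) + m
    # tied times share a risk set
    grp_end = np.empty(len(t), dtype=int)
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] == t[i]:
            j += 1
        grp_end[i : j + 1] = j
        i = j + 1
    ev = d == 1
    return float((e[ev] - cum[grp_end][ev]).sum())


def _risk_set_sums(x_sorted: np.ndarray, w: np.ndarray, grp_end: np.ndarray):
    """Suffix-style risk-set sums with tie groups, for Newton updates.

    ``x_sorted`` is (n, p); ``w`` is (n, p) of exp(eta).  Returns risk-set
    sums of w, w*x, w*x^2 evaluated at each subject's tie-group end.
    """
    s0 = np.cumsum(w, axis=0)[grp_end]
    s1 = np.cumsum(w * x_sorted, axis=0)[grp_end]
    s2 = np.cumsum(w * x_sorted**2, axis=0)[grp_end]
    return s0, s1, s2


def univariate_cox_filter(
    table: pd.DataFrame, time, event, alpha: float = 0.05,
    max_iter: int = 25, tol: float = 1e-8,
) -> pd.DataFrame:
    """Single-covariate Cox fits for every feature, with Wald p-values.

    Newton-Raphson on the Breslow partial likelihood, vectorized across
    features.  Returns a frame indexed by feature with ``beta``, ``se``,
    ``p``, ``converged`` and ``kept`` (p < alpha and converged; features
    with monotone likelihood are flagged and excluded).
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    if d.sum() < 2:
        raise ValueError("univariate screening needs >= 2 events")
    x = table.to_numpy(dtype=float)
    n, p = x.shape

    order = np.argsort(-t, kind="stable")
    xs = x[order]
    ts = t[order]
    ds = d[order]
    grp_end = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        grp_end[i : j + 1] = j
        i = j + 1
    ev = ds == 1

    beta = np.zeros(p)
    diverged = np.zeros(p, dtype=bool)
    info = np.full(p, np.nan)
    for _ in range(max_iter):
        eta = xs * beta  # (n, p)
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        s0, s1, s2 = _risk_set_sums(xs, w, grp_end)
        mu = s1 / s0
        u = (xs[ev] - mu[ev]).sum(axis=0)  # score
        info = ((s2 / s0 - mu**2)[ev]).sum(axis=0)  # observed information
        bad = ~np.isfinite(u) | ~np.isfinite(info) | (info <= 1e-12)
        diverged |= bad
        step = np.zeros(p)
        good = ~bad
        step[good] = u[good] / info[good]
        step = np.clip(step, -2.0, 2.0)
        beta = beta + np.where(diverged, 0.0, step)
        if np.max(np.abs(step[~diverged]), initial=0.0) < tol:
            break
    se = np.full(p, np.nan)
    ok = ~diverged & (info > 0)
    se[ok] = 1.0 / np.sqrt(info[ok])
    # monotone likelihood: the estimate drifts unboundedly and the
    # information collapses (per-SD covariates make |beta| > 15 pathological)
    diverged |= (np.abs(beta) > 15) | ~np.isfinite(se) | (se > 1e3)
    se[diverged] = np.nan
    with np.errstate(invalid="ignore"):
        pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    out = pd.DataFrame(
        {"beta": beta, "se": se, "p": pvals, "converged": ~diverged},
        index=table.columns,
    )
    out["kept"] = out["converged"] & (out["p"] < alpha)
    n_bad = int(diverged.sum())
    if n_bad:
        warnings.warn(f"{n_bad} feature(s) excluded for non-convergence (monotone likelihood)")
    return out


# ---------------------------------------------------------------------------
# Lasso-Cox


@dataclass
class Signature:
    """A sparse linear prognostic signature with its standardization."""

    names: list[str]
    coefficients: np.ndarray
    stats: pd.DataFrame  # mean/sd per selected feature (training statistics)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.names) != len(self.coefficients):
            raise ValueError("names and coefficients must align")

    def __len__(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "coefficients": self.coefficients.tolist(),
            "mean": self.stats["mean"].tolist(),
            "sd": self.stats["sd"].tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        stats_df = pd.DataFrame({"mean": d["mean"], "sd": d["sd"]}, index=d["names"])
        return cls(list(d["names"]), np.asarray(d["coefficients"]), stats_df)


def signature_score(signature: Signature, rows: pd.DataFrame) -> np.ndarray:
    """Linear-combination risk score of standardized selected features."""
    if len(signature) == 0:
        return np.zeros(len(rows))
    z = apply_zscore(rows, signature.stats)
    return z.to_numpy() @ signature.coefficients


def lasso_cox_select(
    table: pd.DataFrame, time, event, config: SelectionConfig | None = None,
    stats_df: pd.DataFrame | None = None,
) -> Signature:
    """L1-penalized Cox selection with cross-validated penalty choice.

    ``table`` should already be standardized (pass the training statistics
    as ``stats_df`` so the returned Signature can reproduce its score from
    raw features).  The penalty grid is the coxnet path (n_penalties
    log-spaced values down from the all-zero solution); the chosen penalty
    minimizes the summed Verweij-van Houwelingen deviance
    ``-2 [pl_full(beta_k) - pl_train_minus_fold(beta_k)]`` over folds.
    """
    config = config or SelectionConfig()
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    x = table.to_numpy(dtype=float)
    y = Surv.from_arrays(event=d.astype(bool), time=t)
    if stats_df is None:
        stats_df = pd.DataFrame(
            {"mean": np.zeros(x.shape[1]), "sd": np.ones(x.shape[1])}, index=table.columns
        )

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=config.n_penalties,
        alpha_min_ratio=config.penalty_min_ratio, fit_baseline_model=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(x, y)
    alphas = np.asarray(path.alphas_)

    kf = KFold(n_splits=config.cv_folds, shuffle=True,
               random_state=config.seed % (2**31))
    fold_dev = []
    valid = np.ones(len(alphas), dtype=bool)
    for train_i, _ in kf.split(x):
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fold.fit(x[train_i], y[train_i])
            except Exception:
                continue
        fold_alphas = list(np.asarray(fold.alphas_))
        row = np.full(len(alphas), np.nan)
        for k, a in enumerate(alphas):
            # coxnet may truncate the requested path; skip missing penalties
            match = [i for i, fa in enumerate(fold_alphas) if np.isclose(fa, a)]
            if not match:
                valid[k] = False
                continue
            beta = fold.coef_[:, match[0]]
            pl_full = breslow_loglik(x @ beta, t, d)
            pl_train = breslow_loglik(x[train_i] @ beta, t[train_i], d[train_i])
            row[k] = -2.0 * (pl_full - pl_train)
        fold_dev.append(row)
    if not fold_dev or not valid.any():
        raise RuntimeError("cross-validation failed on every penalty")
    fold_dev = np.asarray(fold_dev)
    mean_dev = np.nanmean(fold_dev, axis=0)
    se_dev = np.nanstd(fold_dev, axis=0, ddof=1) / np.sqrt(len(fold_dev))
    mean_dev[~valid] = np.inf
    k_min = int(np.argmin(mean_dev))
    if config.penalty_rule == "1se":
        # sparsest (largest) penalty within one SE of the minimum deviance
        threshold = mean_dev[k_min] + se_dev[k_min]
        candidates = np.flatnonzero(valid & (mean_dev <= threshold))
        k_best = int(candidates[np.argmax(alphas[candidates])])
    else:
        k_best = k_min
    best = alphas[k_best]

    def _fit_at(alpha):
        final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha], fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final.fit(x, y)
        return final.coef_[:, 0]

    coefs = _fit_at(best)
    nz = np.flatnonzero(coefs != 0)
    if len(nz) == 0 and config.penalty_rule == "1se" and k_best != k_min:
        # the sparser 1-SE choice degenerated to the null model: fall back to
        # the deviance minimizer rather than returning nothing
        warnings.warn("1-SE penalty selected no features; falling back to the CV minimum")
        coefs = _fit_at(alphas[k_min])
        nz = np.flatnonzero(coefs != 0)
    if len(nz) == 0:
        warnings.warn("Lasso-Cox selected no features (all coefficients zero)")
        return Signature([], np.array([]), stats_df.iloc[:0])
    names = [table.columns[i] for i in nz]
    return Signature(names, coefs[nz], stats_df.loc[names])
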