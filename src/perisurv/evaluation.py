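"""Discrimination, calibration, and stratified survival analysis of risk scores.

Conventions
-----------
* Harrell's C: over comparable pairs (i, j) with T_i < T_j and delta_i = 1,
  a pair is concordant when the shorter-lived subject has the higher score;
  score ties earn 0.5 credit; pairs tied on time with both events are
  excluded.
* Time-dependent AUC: cumulative-cases / dynamic-controls with inverse
  probability of censoring weights (via scikit-survival).
* DeLong is applied to the horizon-dichotomized outcome, excluding subjects
  censored before the horizon.
* Bootstrap: subject-level resampling, percentile intervals, seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

__all__ = [
    "harrell_cindex",
    "bootstrap_ci",
    "time_dependent_auc",
    "delong_compare",
    "horizon_status",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "calibration_curve",
    "subgroup_report",
    "EvalReport",
    "evaluate_risk_score",
]

DEFAULT_HORIZONS = (365.0, 730.0, 1095.0)


# ---------------------------------------------------------------------------
# concordance


def harrell_cindex(scores, time, event) -> float:
    """Harrell's concordance index of a risk score (higher score = higher risk)."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if s.ndim != 1 or s.shape != t.shape or t.shape != e.shape:
        raise ValueError("scores, time and event must be 1-D and aligned")
    # pair (i, j) comparable iff t_i < t_j and e_i == 1
    ti, tj = t[:, None], t[None, :]
    comparable = (ti < tj) & (e[:, None] == 1)
    if not comparable.any():
        raise ValueError("no comparable pairs (need at least one event before another time)")
    si, sj = s[:, None], s[None, :]
    credit = np.where(si > sj, 1.0, np.where(si == sj, 0.5, 0.0))
    return float((credit * comparable).sum() / comparable.sum())


def bootstrap_ci(stat_fn, n: int, n_boot: int = 1000, seed: int = 0, level: float = 0.95):
    """Percentile bootstrap CI for a statistic of subject indices.

    ``stat_fn(idx)`` evaluates the statistic on a resample given integer
    indices; undefined resamples (raising ValueError) are skipped.
    """
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            vals.append(stat_fn(idx))
        except ValueError:
            continue
    if not vals:
        return (np.nan, np.nan)
    lo, hi = np.percentile(vals, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return (float(lo), float(hi))


def harrell_cindex_ci(scores, time, event, n_boot: int = 1000, seed: int = 0):
    s, t, e = map(np.asarray, (scores, time, event))
    c = harrell_cindex(s, t, e)
    ci = bootstrap_ci(lambda idx: harrell_cindex(s[idx], t[idx], e[idx]), len(s), n_boot, seed)
    return c, ci


# ---------------------------------------------------------------------------
# time-dependent AUC


def time_dependent_auc(scores, time, event, horizon: float) -> float:
    """Cumulative/dynamic AUC at a horizon with IPCW from the KM censoring estimator."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    cases = e & (t <= horizon)
    controls = t > horizon
    if not cases.any() or not controls.any():
        raise ValueError(f"degenerate horizon {horizon}: need at least one case and one control")
    y = Surv.from_arrays(event=e, time=t)
    auc, _ = cumulative_dynamic_auc(y, y, np.asarray(scores, dtype=float), [horizon])
    return float(auc[0])


def time_dependent_auc_ci(scores, time, event, horizon, n_boot: int = 1000, seed: int = 0):
    s, t, e = map(np.asarray, (scores, time, event))
    a = time_dependent_auc(s, t, e, horizon)
    ci = bootstrap_ci(lambda i: time_dependent_auc(s[i], t[i], e[i], horizon), len(s), n_boot, seed)
    return a, ci


# ---------------------------------------------------------------------------
# DeLong


def horizon_status(time, event, horizon: float) -> np.ndarray:
    """Dichotomize survival at a horizon: 1 = event by horizon, 0 = survived past.

    Subjects censored at or before the horizon are unknown -> NaN.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    status = np.full(len(t), np.nan)
    status[(e == 1) & (t <= horizon)] = 1.0
    status[t > horizon] = 0.0
    return status


def _placements(x_cases, x_controls):
    """Placement values (mid-rank convention) for the DeLong variance."""
    v_cases = np.array([(np.sum(c > x_controls) + 0.5 * np.sum(c == x_controls)) for c in x_cases])
    v_controls = np.array([(np.sum(x_cases > d) + 0.5 * np.sum(x_cases == d)) for d in x_controls])
    return v_cases / len(x_controls), v_controls / len(x_cases)


def delong_compare(scores_a, scores_b, outcome) -> tuple[float, float, float, float]:
    """Paired DeLong test for the difference between two AUCs.

    Returns ``(auc_a, auc_b, z, p)``; subjects with NaN outcome (unknown
    status at the horizon) are dropped from both score sets.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcome, dtype=float)
    keep = ~np.isnan(y)
    a, b, y = a[keep], b[keep], y[keep].astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both outcome classes for DeLong")
    cases, controls = y == 1, y == 0
    m, n = cases.sum(), controls.sum()

    aucs, v10s, v01s = [], [], []
    for s in (a, b):
        v10, v01 = _placements(s[cases], s[controls])
        aucs.append(v10.mean())
        v10s.append(v10)
        v01s.append(v01)
    v10s = np.vstack(v10s)
    v01s = np.vstack(v01s)
    s10 = np.cov(v10s) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01s) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        warnings.warn("zero DeLong variance; reporting p = 1")
        return float(aucs[0]), float(aucs[1]), 0.0, 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(z), float(p)


# ---------------------------------------------------------------------------
# KM / log-rank / HR


def km_estimate(time, event, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit estimates per group as (time, at_risk, events, survival) tables."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.zeros(len(t), dtype=int) if groups is None else np.asarray(groups)
    out = {}
    for label in np.unique(g):
        sel = g == label
        if not sel.any():
            continue
        kmf = KaplanMeierFitter().fit(t[sel], e[sel])
        tab = kmf.event_table
        out[str(label)] = pd.DataFrame(
            {
                "time": tab.index.to_numpy(dtype=float),
                "at_risk": tab["at_risk"].to_numpy(),
                "events": tab["observed"].to_numpy(),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            }
        )
    return out


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if e.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = _ll_logrank(t[g == labels[0]], t[g == labels[1]], e[g == labels[0]], e[g == labels[1]])
    return float(res.test_statistic), float(res.p_value)


def hazard_ratio(time, event, groups) -> dict:
    """Binary-covariate Cox fit: HR of group 1 vs group 0 with Wald 95% CI."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("hazard_ratio needs exactly 2 groups")
    x = (g == labels[1]).astype(float)
    events_per_group = [e[x == v].sum() for v in (0, 1)]
    if 0 in events_per_group:
        warnings.warn("one group is event-free: monotone likelihood, HR unbounded")
        hr = np.inf if events_per_group[0] == 0 else 0.0
        return {"hr": hr, "ci": (np.nan, np.nan), "beta": np.nan, "se": np.nan, "monotone": True}
    df = pd.DataFrame({"x": x, "T": t, "E": e})
    fit = CoxPHFitter().fit(df, "T", "E")
    beta = float(fit.params_["x"])
    se = float(fit.standard_errors_["x"])
    return {
        "hr": float(np.exp(beta)),
        "ci": (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        "beta": beta,
        "se": se,
        "monotone": False,
    }


# ---------------------------------------------------------------------------
# calibration


def calibration_curve(
    predicted_survival,
    time,
    event,
    horizon: float,
    n_bins: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted vs observed survival probability at a horizon.

    Subjects are binned by predicted survival (quantile bins; empty or
    single-subject bins are merged with their neighbour); observed survival
    is the KM estimate per bin at the horizon, with percentile bootstrap
    bands over subject resamples.
    """
    p = np.asarray(predicted_survival, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        bins = np.zeros(len(p), dtype=int)
    else:
        bins = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)

    def km_at(tt, ee, horizon):
        kmf = KaplanMeierFitter().fit(tt, ee)
        return float(kmf.predict(horizon))

    rows = []
    rng = np.random.default_rng(seed)
    for b in np.unique(bins):
        sel = bins == b
        obs = km_at(t[sel], e[sel], horizon)
        boots = []
        idx_pool = np.flatnonzero(sel)
        for _ in range(n_boot):
            idx = rng.choice(idx_pool, size=len(idx_pool), replace=True)
            try:
                boots.append(km_at(t[idx], e[idx], horizon))
            except Exception:
                continue
        lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
        rows.append(
            {
                "bin": int(b),
                "n": int(sel.sum()),
                "predicted": float(p[sel].mean()),
                "observed": obs,
                "observed_lo": float(lo),
                "observed_hi": float(hi),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvalReport:
    """Evaluation of one risk score on one dataset."""

    cindex: float
    cindex_ci: tuple[float, float]
    auc: dict[float, float]
    auc_ci: dict[float, tuple[float, float]]
    logrank_stat: float | None = None
    logrank_p: float | None = None
    hr: dict | None = None
    km: dict | None = None
    subgroups: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "cindex": self.cindex,
            "cindex_ci": list(self.cindex_ci),
            "auc": {str(int(h)): v for h, v in self.auc.items()},
            "auc_ci": {str(int(h)): list(v) for h, v in self.auc_ci.items()},
        }
        if self.logrank_p is not None:
            out["logrank"] = {"stat": self.logrank_stat, "p": self.logrank_p}
        if self.hr is not None:
            out["hazard_ratio"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.hr.items()}
        if self.subgroups:
            out["subgroups"] = self.subgroups
        return out


def evaluate_risk_score(
    scores,
    time,
    event,
    horizons=DEFAULT_HORIZONS,
    risk_groups=None,
    strata: pd.DataFrame | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> EvalReport:
    """Full discrimination + stratification report for a risk score.

    ``risk_groups`` (e.g. median-split labels) enables KM/log-rank/HR;
    ``strata`` (a frame of categorical columns) adds subgroup sub-reports.
    """
    s, t, e = (np.asarray(v) for v in (scores, time, event))
    c, c_ci = harrell_cindex_ci(s, t, e, n_boot=n_boot, seed=seed)
    auc, auc_ci = {}, {}
    for h in horizons:
        try:
            a, ci = time_dependent_auc_ci(s, t, e, h, n_boot=n_boot, seed=seed)
        except ValueError:
            a, ci = np.nan, (np.nan, np.nan)
        auc[float(h)] = a
        auc_ci[float(h)] = ci
    report = EvalReport(c, c_ci, auc, auc_ci)
    if risk_groups is not None:
        g = np.asarray(risk_groups)
        report.logrank_stat, report.logrank_p = logrank_test(t, e, g)
        report.hr = hazard_ratio(t, e, g)
        report.km = km_estimate(t, e, g)
        if strata is not None:
            report.subgroups = subgroup_report(g, t, e, strata)
    return report


def subgroup_report(risk_groups, time, event, strata: pd.DataFrame) -> dict:
    """KM + log-rank + HR of the risk grouping within each clinical stratum.

    Strata where a level lacks both risk groups or any event are reported
    as not evaluable rather than failing.
    """
    g = np.asarray(risk_groups)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    out: dict[str, dict] = {}
    for col in strata.columns:
        col_report = {}
        for level in pd.unique(strata[col]):
            sel = (strata[col] == level).to_numpy()
            key = str(level)
            if len(np.unique(g[sel])) < 2 or e[sel].sum() == 0:
                col_report[key] = {"evaluable": False, "n": int(sel.sum())}
                continue
            stat, p = logrank_test(t[sel], e[sel], g[sel])
            hr = hazard_ratio(t[sel], e[sel], g[sel])
            col_report[key] = {
                "evaluable": True,
                "n": int(sel.sum()),
                "logrank_stat": stat,
                "logrank_p": p,
                "hr": hr["hr"],
                "hr_ci": list(hr["ci"]),
            }
        out[col] = col_report
    return out
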