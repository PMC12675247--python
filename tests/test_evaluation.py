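"""Survival evaluation suite against brute-force and hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perisurv.evaluation import (
    calibration_curve,
    delong_compare,
    harrell_cindex,
    hazard_ratio,
    horizon_status,
    km_estimate,
    logrank_test,
    subgroup_report,
    time_dependent_auc,
    evaluate_risk_score,
)


def brute_force_cindex(s, t, e):
    """Oracle: explicit double loop over ordered pairs."""
    num = den = 0.0
    n = len(s)
    for i in range(n):
        for j in range(n):
            if t[i] < t[j] and e[i] == 1:
                den += 1
                if s[i] > s[j]:
                    num += 1
                elif s[i] == s[j]:
                    num += 0.5
    return num / den


class TestCindex:
    def test_perfect_and_tied(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrell_cindex(-t, t, np.ones(4, int)) == 1.0
        assert harrell_cindex(np.zeros(4), t, np.ones(4, int)) == 0.5

    def test_five_subject_mixed_censoring(self):
        s = np.array([2.0, 1.0, 3.0, 1.0, 0.0])
        t = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1, 0])
        assert harrell_cindex(s, t, e) == brute_force_cindex(s, t, e)

    def test_matches_brute_force_on_random_small_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(2, 9)
            s = rng.choice([0.0, 0.5, 1.0, 2.0], size=n)
            t = rng.choice([1.0, 2.0, 3.0], size=n)
            e = rng.integers(0, 2, size=n)
            if not ((t[:, None] < t[None, :]) & (e[:, None] == 1)).any():
                continue
            assert harrell_cindex(s, t, e) == pytest.approx(brute_force_cindex(s, t, e), abs=1e-12)

    def test_agrees_with_scikit_survival(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(1)
        n = 300
        s = rng.normal(size=n)
        t = rng.exponential(100, n)
        e = rng.integers(0, 2, n).astype(bool)
        ours = harrell_cindex(s, t, e.astype(int))
        ref = concordance_index_censored(e, t, s)[0]
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_cindex([1.0, 2.0], [1.0, 1.0], [1, 1])


class TestTimeDependentAUC:
    def test_reduces_to_binary_auc_without_censoring(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        n = 200
        s = rng.normal(size=n)
        t = rng.exponential(100, n) + 1
        e = np.ones(n, int)
        h = float(np.median(t))
        auc = time_dependent_auc(s, t, e, h)
        y = (t <= h).astype(int)
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-10)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(50):
            n = 500
            s = rng.normal(size=n)
            t = rng.exponential(500, n) + 1
            e = (rng.random(n) < 0.7).astype(int)
            aucs.append(time_dependent_auc(s, t, e, 365.0))
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_monotone_score_perfect(self):
        t = np.linspace(10, 1000, 50)
        assert time_dependent_auc(-t, t, np.ones(50, int), 500.0) == pytest.approx(1.0)

    def test_degenerate_horizon_rejected(self):
        with pytest.raises(ValueError):
            time_dependent_auc([1.0, 2.0], [10.0, 20.0], [1, 1], 5.0)


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        with pytest.warns(UserWarning):
            *_, p = delong_compare(s, s, y)
        assert p == 1.0

    def test_hand_computed_four_subjects(self):
        # A: cases score (3, 1), controls (2, 0): placements (1.0, 0.5) -> AUC 0.75
        # B: cases score (2, 1), controls (3, 0): placements (0.5, 0.5) -> AUC 0.50
        a = np.array([3.0, 1.0, 2.0, 0.0])
        b = np.array([2.0, 1.0, 3.0, 0.0])
        y = np.array([1, 1, 0, 0])
        auc_a, auc_b, z, p = delong_compare(a, b, y)
        assert auc_a == pytest.approx(0.75)
        assert auc_b == pytest.approx(0.50)
        assert 0 < p <= 1

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            n = 120
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            ps.append(delong_compare(a, b, y)[3])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_censored_subjects_excluded_via_nan(self):
        y = horizon_status([100, 400, 200, 500], [1, 0, 0, 1], 365.0)
        assert y[0] == 1.0 and np.isnan(y[2])  # censored before horizon unknown
        assert y[1] == 0.0 and y[3] == 0.0  # survived past horizon (t > h)


class TestKMLogrankHR:
    def test_km_product_limit_by_hand(self):
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])["0"]
        # first row is t=0 with S=1; successive events then drop by 1/4
        assert np.allclose(km["survival"], [1.0, 0.75, 0.5, 0.25, 0.0])
        assert np.all(np.diff(km["survival"]) <= 0)

    def test_all_censored_flat_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])["0"]
        assert np.allclose(km["survival"], 1.0)

    def test_logrank_hand_accumulated_six_subjects(self):
        # group 0: events at 1, 2; censored 3.  group 1: events at 4, 5; censored 6
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        # hand accumulation for group 1 over event times 1, 2, 4, 5:
        #   t=1: at risk 3/6, O-E = 0 - 1/2,  var = (3/6)(3/6) = 1/4
        #   t=2: at risk 3/5, O-E = 0 - 3/5,  var = (2/5)(3/5) = 6/25
        #   t=4: only group 1 at risk (group 0 exhausted): O-E = 0, var = 0
        #   t=5: likewise 0
        o_minus_e = -0.5 - 0.6
        v = 0.25 + 0.24
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(o_minus_e**2 / v, rel=1e-6)

    def test_logrank_label_permutation_symmetry(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(100, 40)
        e = rng.integers(0, 2, 40)
        e[:5] = 1
        g = rng.integers(0, 2, 40)
        s1, _ = logrank_test(t, e, g)
        s2, _ = logrank_test(t, e, 1 - g)
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_hr_recovery_and_symmetry(self):
        rng = np.random.default_rng(7)
        hits = 0
        for r in range(10):
            n = 1000
            g = rng.integers(0, 2, n)
            t = rng.exponential(np.where(g == 1, 0.5, 1.0))
            e = np.ones(n, int)
            hr = hazard_ratio(t, e, g)
            if 1.7 <= hr["hr"] <= 2.3:
                hits += 1
        assert hits >= 9
        # swapping labels inverts the HR
        hr0 = hazard_ratio(t, e, g)
        hr1 = hazard_ratio(t, e, 1 - g)
        assert hr0["hr"] * hr1["hr"] == pytest.approx(1.0, abs=1e-6)

    def test_event_free_group_flagged(self):
        with pytest.warns(UserWarning, match="monotone"):
            hr = hazard_ratio([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], [0, 0, 1, 1])
        assert hr["monotone"] and hr["hr"] == 0.0

    def test_logrank_hr_directional_agreement(self):
        rng = np.random.default_rng(8)
        for r in range(10):
            n = 200
            g = rng.integers(0, 2, n)
            t = rng.exponential(np.where(g == 1, 0.6, 1.0))
            e = np.ones(n, int)
            hr = hazard_ratio(t, e, g)
            km = km_estimate(t, e, g)
            # HR > 1 for group 1 <=> group 1 dies faster (lower survival)
            s1 = km["1"]["survival"].iloc[len(km["1"]) // 2]
            s0_interp = np.interp(km["1"]["time"].iloc[len(km["1"]) // 2],
                                  km["0"]["time"], km["0"]["survival"])
            assert (hr["hr"] > 1) == (s1 < s0_interp)


class TestCalibrationAndReports:
    def test_constant_prediction_single_bin_equals_km(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(400, 200)
        e = (rng.random(200) < 0.7).astype(int)
        cal = calibration_curve(np.full(200, 0.6), t, e, horizon=365.0, n_boot=50)
        assert len(cal) == 1
        km = km_estimate(t, e)["0"]
        s_at = np.interp(365.0, km["time"], km["survival"])
        assert cal["observed"].iloc[0] == pytest.approx(s_at, abs=0.02)
        assert cal["observed_lo"].iloc[0] <= cal["observed"].iloc[0] <= cal["observed_hi"].iloc[0]

    def test_self_consistent_simulation_calibrated(self):
        # survival drawn from the very model used for prediction
        rng = np.random.default_rng(10)
        n = 1000
        eta = rng.normal(size=n)
        s_pred_at = np.exp(-(365.0 / 500.0) * np.exp(eta))  # exponential PH
        t = rng.exponential(500.0 * np.exp(-eta))
        e = np.ones(n, int)
        cal = calibration_curve(s_pred_at, t, e, horizon=365.0, n_boot=50)
        assert (cal["predicted"] - cal["observed"]).abs().mean() < 0.05

    def test_evaluate_risk_score_and_subgroups(self):
        rng = np.random.default_rng(11)
        n = 300
        eta = rng.normal(size=n)
        t = rng.exponential(500.0 * np.exp(-eta))
        e = (rng.random(n) < 0.8).astype(int)
        groups = (eta > np.median(eta)).astype(int)
        strata = pd.DataFrame({"sex": rng.choice(["m", "f"], n)})
        rep = evaluate_risk_score(eta, t, e, horizons=(365.0,), risk_groups=groups,
                                  strata=strata, n_boot=20, seed=0)
        d = rep.to_dict()
        assert 0.5 < d["cindex"] <= 1.0
        assert d["hazard_ratio"]["hr"] > 1.0
        assert d["logrank"]["p"] < 0.01
        assert set(d["subgroups"]["sex"]) == {"m", "f"}

    def test_degenerate_stratum_marked_not_evaluable(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        g = np.array([0, 1, 0, 1])
        strata = pd.DataFrame({"grp": ["a", "a", "b", "b"], "solo": ["x", "x", "x", "x"]})
        rep = subgroup_report(np.array([0, 0, 1, 1]), t, e, strata)
        assert rep["grp"]["a"]["evaluable"] is False  # only one risk group present
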