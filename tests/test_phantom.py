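"""Synthetic cohort generator: geometry, planted survival model, determinism."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import ndimage, stats

from perisurv.phantom import (
    COVARIATE_NAMES,
    PhantomSpec,
    SimulationTruth,
    generate_cohort,
    generate_phantom,
    simulate_survival,
    write_cohort,
)


class TestGeneratePhantom:
    def test_mask_single_component_and_intensities(self, small_spec, small_phantom):
        vol, gtv, cov = small_phantom
        mask = gtv.data.astype(bool)
        _, n_comp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
        assert n_comp == 1
        tumor_vals = vol.data[mask]
        assert abs(tumor_vals.mean() - small_spec.tumor_mean_intensity) < 5 * cov["texture_contrast"]
        # background far from the tumor is lung-like
        far = ~ndimage.binary_dilation(mask, iterations=12)
        assert abs(vol.data[far].mean() - small_spec.background_mean) < 10

    def test_zero_texture_contrast_gives_exact_tumor_mean(self):
        spec = PhantomSpec(
            volume_shape=(48, 48, 48),
            tumor_radius_range_mm=(6.0, 6.0),
            texture_contrast_range=(0.0, 0.0),
        )
        vol, gtv, _ = generate_phantom(spec, seed=3)
        assert np.all(vol.data[gtv.data.astype(bool)] == spec.tumor_mean_intensity)

    def test_zero_rim_width_leaves_background_untouched(self):
        spec = PhantomSpec(
            volume_shape=(48, 48, 48),
            tumor_radius_range_mm=(6.0, 6.0),
            rim_width_range_mm=(0.0, 0.0),
        )
        vol, gtv, _ = generate_phantom(spec, seed=3)
        mask = gtv.data.astype(bool)
        border = ndimage.binary_dilation(mask) & ~mask
        vals = vol.data[border]
        # first voxels outside the mask follow the background distribution
        assert abs(vals.mean() - spec.background_mean) < 5 * spec.background_sd / np.sqrt(len(vals))

    def test_sphere_volume_matches_lattice_enumeration(self):
        spec = PhantomSpec(
            volume_shape=(48, 48, 48),
            tumor_radius_range_mm=(8.0, 8.0),
            rim_width_range_mm=(0.0, 0.0),
        )
        _, gtv, cov = generate_phantom(spec, seed=11)
        n_vox = int(gtv.data.sum())
        analytic = 4.0 / 3.0 * np.pi * 8.0**3
        assert abs(n_vox - analytic) / analytic < 0.05
        assert np.isclose(cov["log_tumor_volume"], np.log(n_vox))

    def test_oversized_tumor_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(volume_shape=(32, 32, 32), tumor_radius_range_mm=(5.0, 20.0))

    def test_determinism(self, small_spec):
        a = generate_phantom(small_spec, seed=5)
        b = generate_phantom(small_spec, seed=5)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
        assert a[2] == b[2]


class TestSimulateSurvival:
    def _covariates(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, 3)), columns=list(COVARIATE_NAMES))

    def test_null_betas_give_weibull_marginal(self):
        truth = SimulationTruth(beta=(0, 0, 0), weibull_shape=1.2, weibull_scale_days=700,
                                censoring_window_days=(1e7, 1e7 + 1))  # effectively no censoring
        surv = simulate_survival(self._covariates(2000), truth, seed=1)
        ks = stats.kstest(surv["time_days"], "weibull_min", args=(1.2, 0, 700))
        assert ks.pvalue > 0.01

    def test_cox_recovers_planted_beta(self):
        truth = SimulationTruth(beta=(1.0, 0.0, 0.0), censoring_window_days=(1e7, 1e7 + 1))
        cov = self._covariates(2000, seed=2)
        surv = simulate_survival(cov, truth, seed=2)
        z = (cov - cov.mean()) / cov.std(ddof=0)
        df = pd.DataFrame({"x": z[COVARIATE_NAMES[0]], "T": surv["time_days"], "E": surv["event"]})
        fit = CoxPHFitter().fit(df, "T", "E")
        assert abs(fit.params_["x"] - 1.0) < 0.1

    def test_full_censoring(self):
        truth = SimulationTruth(beta=(0, 0, 0), weibull_shape=5.0, weibull_scale_days=10_000,
                                censoring_window_days=(1.0, 2.0))
        surv = simulate_survival(self._covariates(200), truth, seed=3)
        assert (surv["event"] == 0).all()
        assert (surv["time_days"] <= 2.0).all()

    def test_invalid_weibull_rejected(self):
        with pytest.raises(ValueError):
            SimulationTruth(weibull_shape=0.0)


class TestGenerateCohort:
    def test_survival_table_byte_identical(self, tmp_path, small_spec):
        c1 = generate_cohort(10, small_spec, seed=1, out_dir=tmp_path / "a")
        c2 = generate_cohort(10, small_spec, seed=1, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "survival.csv").read_bytes() == (tmp_path / "b" / "survival.csv").read_bytes()
        assert np.array_equal(c1.volumes[0].data, c2.volumes[0].data)

    def test_minimum_cohort_and_rejection(self, small_spec):
        cohort = generate_cohort(2, small_spec, seed=4)
        assert len(cohort) == 2 and {"time_days", "event"} <= set(cohort.table.columns)
        with pytest.raises(ValueError):
            generate_cohort(1, small_spec, seed=4)

    def test_censoring_fraction_matches_monte_carlo_target(self, small_spec):
        truth = SimulationTruth()
        cohort = generate_cohort(200, small_spec, truth=truth, seed=9)
        observed = 1.0 - cohort.table["event"].mean()

        # independent Monte-Carlo integration of P(C < T) under the planted model
        rng = np.random.default_rng(123)
        n_mc = 100_000
        cov = cohort.table[[f"truth_{c}" for c in COVARIATE_NAMES]].to_numpy()
        z = (cov - cov.mean(0)) / cov.std(0)
        eta = z[rng.integers(0, len(z), n_mc)] @ np.array(truth.beta)
        t = truth.weibull_scale_days * (rng.exponential(size=n_mc) * np.exp(-eta)) ** (1 / truth.weibull_shape)
        c = rng.uniform(*truth.censoring_window_days, size=n_mc)
        target = np.mean(c < t)
        assert abs(observed - target) < 0.10

    def test_planted_model_is_proportional_hazards(self):
        """Schoenfeld-style trend test finds no systematic PH violation."""
        from lifelines.statistics import proportional_hazard_test

        truth = SimulationTruth(beta=(1.0, 0.0, 0.0))
        rng = np.random.default_rng(21)
        cov = pd.DataFrame(rng.normal(size=(2000, 3)), columns=list(COVARIATE_NAMES))
        surv = simulate_survival(cov, truth, seed=21)
        z = (cov - cov.mean()) / cov.std(ddof=0)
        df = pd.DataFrame({"x": z[COVARIATE_NAMES[0]], "T": surv["time_days"], "E": surv["event"]})
        fit = CoxPHFitter().fit(df, "T", "E")
        res = proportional_hazard_test(fit, df, time_transform="rank")
        assert res.p_value[0] > 0.01

    def test_planted_signal_monotone_in_beta(self, small_spec):
        """Stronger planted coefficients raise the C-index of the true predictor."""
        from perisurv.evaluation import harrell_cindex

        cs = []
        for b in (0.3, 1.2):
            truth = SimulationTruth(beta=(b, 0.2, 0.2))
            rng = np.random.default_rng(11)
            cov = pd.DataFrame(rng.normal(size=(2000, 3)), columns=list(COVARIATE_NAMES))
            surv = simulate_survival(cov, truth, seed=11)
            z = (cov - cov.mean()) / cov.std(ddof=0)
            eta = z.to_numpy() @ np.array(truth.beta)
            cs.append(harrell_cindex(eta, surv["time_days"].to_numpy(), surv["event"].to_numpy()))
        assert cs[1] > cs[0]
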