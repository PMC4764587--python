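"""Observer MLE, BIC comparison, saccade-noise regression."""

import numpy as np
import pandas as pd
import pytest

from actsense import (
    ObserverParams,
    PriorBias,
    SaccadeNoiseModel,
    fit_saccade_model,
    mc_choice_loglik,
    simulate_saccade_calibration,
)
from actsense.fitting import (
    MAD_TO_SD,
    ModelVariant,
    ObserverDecisionModel,
    SaccadeCalibration,
    all_variants,
    bic_table,
    fit_variant,
)


class TestModelVariants:
    def test_exactly_six_variants(self):
        variants = all_variants()
        assert len(variants) == 6
        assert len({v.label for v in variants}) == 6

    def test_parameter_counts(self):
        assert ModelVariant("none", False).n_params == 2
        assert ModelVariant("offset", False).n_params == 3
        assert ModelVariant("scale", True).n_params == 4


class TestMcChoiceLoglik:
    def test_noise_free_likelihood_is_independent_of_n_sims(self, random_trials_small):
        """sigma_p = 0: every redraw is the displayed value, so n_sims is moot.

        n_sims is kept large enough that the 1/(10 n_sims) probability floor
        stays below the kappa/2 lower bound of the choice probability.
        """
        params = ObserverParams(sigma_p=0.0, beta=1.5, kappa=0.1)
        lls = [
            mc_choice_loglik(random_trials_small, params, n_sims=n, rng=np.random.default_rng(3))
            for n in (10, 50, 200)
        ]
        assert lls[0] == pytest.approx(lls[1], abs=1e-9)
        assert lls[0] == pytest.approx(lls[2], abs=1e-9)

    def test_full_lapse_likelihood_is_exactly_coin_flipping(self, random_trials_small):
        params = ObserverParams(sigma_p=0.5, beta=1.5, kappa=1.0)
        ll = mc_choice_loglik(random_trials_small, params, n_sims=20, rng=np.random.default_rng(0))
        assert ll == pytest.approx(len(random_trials_small) * np.log(0.5), abs=1e-9)

    def test_common_random_numbers_make_the_likelihood_deterministic(self, random_trials_small):
        params = ObserverParams(sigma_p=0.4, prior_bias=PriorBias("offset", 0.3), beta=2.0)
        a = mc_choice_loglik(random_trials_small, params, n_sims=30, rng=np.random.default_rng(9))
        b = mc_choice_loglik(random_trials_small, params, n_sims=30, rng=np.random.default_rng(9))
        assert a == b

    def test_mc_error_shrinks_with_n_sims(self, random_trials_small):
        """SD of the MC log-likelihood over seeds scales roughly as 1/sqrt(n_sims)."""
        params = ObserverParams(sigma_p=0.6, beta=1.5, kappa=0.05)

        def sd(n_sims):
            lls = [
                mc_choice_loglik(random_trials_small, params, n_sims=n_sims,
                                 rng=np.random.default_rng(s))
                for s in range(12)
            ]
            return np.std(lls, ddof=1)

        sd_small, sd_big = sd(50), sd(800)
        ratio = sd_small / sd_big
        assert 2.0 < ratio < 8.0  # ideal sqrt(16) = 4


class TestFitVariant:
    def test_reported_sigma_p_is_a_grid_value(self, random_trials_small):
        grids = {"sigma_p": np.array([0.3, 0.5, 0.7]), "delta": np.array([0.0, 0.6])}
        res = fit_variant(
            random_trials_small, ModelVariant("offset", True), grids=grids, n_sims=20, seed=0
        )
        assert res.params.sigma_p in grids["sigma_p"]
        assert res.params.prior_bias.value in grids["delta"]
        assert res.bic == pytest.approx(4 * np.log(60) - 2 * res.loglik)

    def test_seeded_fit_is_reproducible(self, random_trials_small):
        grids = {"sigma_p": np.array([0.4, 0.6]), "delta": np.array([0.3, 0.9])}
        a = fit_variant(random_trials_small, ModelVariant("offset", False), grids=grids, n_sims=15, seed=4)
        b = fit_variant(random_trials_small, ModelVariant("offset", False), grids=grids, n_sims=15, seed=4)
        assert a.loglik == b.loglik and a.params == b.params

    def test_boundary_optimum_is_flagged(self, random_trials_small):
        grids = {"sigma_p": np.array([1.4, 1.5])}  # far from the generating 0.5
        res = fit_variant(random_trials_small, ModelVariant("none", False), grids=grids, n_sims=10, seed=0)
        assert res.diagnostics.get("sigma_p_on_boundary")

    def test_likelihood_peaks_near_the_generating_parameters(self, random_trials_small):
        """Generating (sigma_p, Delta) beats a 3-grid-step perturbation."""
        gen = ObserverParams(sigma_p=0.5, prior_bias=PriorBias("offset", 0.6), beta=1.5, kappa=0.05)
        off = ObserverParams(sigma_p=0.8, prior_bias=PriorBias("offset", 1.5), beta=1.5, kappa=0.05)
        rng = np.random.default_rng(6)
        ll_gen = mc_choice_loglik(random_trials_small, gen, n_sims=50, rng=np.random.default_rng(6))
        ll_off = mc_choice_loglik(random_trials_small, off, n_sims=50, rng=np.random.default_rng(6))
        assert ll_gen > ll_off


class TestBicTable:
    def test_best_row_has_zero_delta_and_penalty_orders_equal_likelihoods(self, random_trials_small):
        grids = {"sigma_p": np.array([0.5]), "delta": np.array([0.6]), "alpha": np.array([1.0])}
        results = bic_table(
            random_trials_small,
            variants=[ModelVariant("none", False), ModelVariant("none", True)],
            grids=grids,
            n_sims=15,
            seed=1,
        )
        assert min(r.delta_bic for r in results) == 0.0
        r_free, r_lapse = results
        # lapse can only raise the likelihood, but costs ln(n) in BIC
        assert r_lapse.loglik >= r_free.loglik - 1e-6
        if abs(r_lapse.loglik - r_free.loglik) < 0.5:
            assert r_free.bic < r_lapse.bic


class TestObserverDecisionModel:
    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone

        est = ObserverDecisionModel(bias_kind="scale", n_sims=25, random_state=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_sets_attributes_and_predicts_probabilities(self, random_trials_small):
        grids = {"sigma_p": np.array([0.4, 0.6]), "delta": np.array([0.4, 0.8])}
        est = ObserverDecisionModel(
            bias_kind="offset", include_lapse=True, n_sims=15, grids=grids, random_state=0
        )
        est.fit(random_trials_small)
        assert hasattr(est, "sigma_p_") and hasattr(est, "bic_")
        proba = est.predict_proba(random_trials_small)
        assert proba.shape == (60, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(random_trials_small)) <= {"P", "S"}


class TestSaccadeCalibration:
    @staticmethod
    def deterministic_endpoints(model, n_pairs=20):
        """Endpoint table whose MAD-based SD estimates equal the model SDs exactly.

        Tangential errors sit at bias(d) +/- sd_tan(d)/1.4826 in equal numbers, so
        the median recovers the bias and 1.4826 x MAD recovers sd_tan; likewise
        orthogonally.
        """
        rows = []
        for ecc in (1.39, 2.78, 5.56, 8.34):
            for i in range(n_pairs):
                sign = 1.0 if i % 2 == 0 else -1.0
                tan = model.bias(ecc) + sign * model.sd_tan(ecc) / MAD_TO_SD
                orth = sign * model.sd_orth(ecc) / MAD_TO_SD
                rows.append(
                    {
                        "eccentricity": ecc,
                        "target_x": ecc, "target_y": 0.0,
                        "other_x": 0.0, "other_y": ecc,
                        "endpoint_x": ecc + tan, "endpoint_y": orth,
                        "drift": 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_exact_recovery_from_deterministic_endpoints(self):
        model = SaccadeNoiseModel(0.1, 0.3, 0.02, 0.2, -0.2, -0.3)
        fitted = fit_saccade_model(self.deterministic_endpoints(model))
        for attr in ("sd_tan_slope", "sd_tan_intercept", "sd_orth_slope",
                     "sd_orth_intercept", "bias_slope", "bias_intercept"):
            assert getattr(fitted, attr) == pytest.approx(getattr(model, attr), abs=1e-9)

    def test_decoys_are_excluded_before_fitting(self):
        model = SaccadeNoiseModel.zero()
        df = simulate_saccade_calibration(
            model, 400, np.random.default_rng(1), decoy_fraction=0.1, drift_sd=0.0
        )
        cal = SaccadeCalibration().fit(df)
        assert cal.n_excluded_misdirected_ == int(df["decoy"].sum())

    def test_drift_exclusion_rule(self):
        df = self.deterministic_endpoints(SaccadeNoiseModel.zero())
        df.loc[:4, "drift"] = 1.0  # above the 0.56-deg threshold
        cal = SaccadeCalibration().fit(df)
        assert cal.n_excluded_drift_ == 5

    def test_mad_estimator_is_consistent_for_gaussian_noise(self):
        """1.4826 x MAD recovers the Gaussian SD (no exclusions triggered).

        The non-cued target is placed far away so the misdirection rule cannot
        truncate the error distribution (it does, mildly, at small target
        separations — a property of the rule, not of the estimator).
        """
        model = SaccadeNoiseModel(0.13, 0.41, 0.011, 0.38, -0.23, -0.37)
        rng = np.random.default_rng(2)
        rows = []
        for ecc in (1.39, 2.78, 5.56, 8.34):
            tan = model.bias(ecc) + rng.normal(0, model.sd_tan(ecc), 10_000)
            orth = rng.normal(0, model.sd_orth(ecc), 10_000)
            rows.append(
                pd.DataFrame(
                    {
                        "eccentricity": ecc,
                        "target_x": ecc, "target_y": 0.0,
                        "other_x": -100.0, "other_y": -100.0,
                        "endpoint_x": ecc + tan, "endpoint_y": orth,
                        "drift": 0.0,
                    }
                )
            )
        fitted = fit_saccade_model(pd.concat(rows, ignore_index=True))
        for d in (2.78, 8.34):
            assert fitted.sd_tan(d) == pytest.approx(model.sd_tan(d), rel=0.05)
            assert fitted.sd_orth(d) == pytest.approx(model.sd_orth(d), rel=0.05)
            assert fitted.bias(d) == pytest.approx(model.bias(d), abs=0.05)

    def test_too_few_eccentricities_raise(self):
        df = self.deterministic_endpoints(SaccadeNoiseModel.zero())
        with pytest.raises(ValueError, match="eccentricities"):
            SaccadeCalibration().fit(df[df["eccentricity"] == 1.39])
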