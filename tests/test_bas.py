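"""Active sensor: predictive mixtures, entropy bounds, scores, saccade noise."""

import numpy as np
import pytest

from actsense import (
    DEFAULT_TYPE_SET,
    GaussianMixture,
    ObservationSet,
    ObserverParams,
    SaccadeNoiseModel,
    apply_saccade_noise,
    bas_score,
    category_predictive,
    choose_fixation,
    jensen_entropy,
    max_entropy_score,
    score_map,
    score_oracle,
)
from actsense.bas import _score_terms_exact, _type_components, mixture_entropy
from actsense.kernels import IMAGE_HALF_EXTENT, LengthScales, PatternType, TypeSet
from actsense.observer import binary_entropy_bits, category_posterior
from actsense.simulate import sample_image, simulate_trial
from conftest import random_observations


def random_type_set(rng):
    lam = lambda: rng.uniform(0.7, 5.0)
    return TypeSet(
        (
            PatternType("PA", LengthScales(lam(), lam()), "P"),
            PatternType("SH", LengthScales(lam(), lam()), "S"),
            PatternType("SV", LengthScales(lam(), lam()), "S"),
        )
    )


class TestCategoryPredictive:
    def test_patchy_category_is_a_single_component(self, obs_pair):
        mix = category_predictive((0.5, 0.5), "P", obs_pair, sigma_p=0.3)
        assert len(mix) == 1 and mix.weights[0] == pytest.approx(1.0)

    def test_stripy_empty_set_is_an_even_prior_mixture(self):
        mix = category_predictive((0.0, 0.0), "S", ObservationSet(), sigma_p=0.5)
        assert mix.weights == pytest.approx([0.5, 0.5])
        assert mix.means == pytest.approx([0.0, 0.0])
        assert mix.variances == pytest.approx([1.25, 1.25])

    def test_stripy_weights_match_marginal_likelihoods(self, rng):
        """Mixture weights are the normalized exp(log marginal) of the stripy types."""
        from actsense.kernels import log_marginal

        D = random_observations(rng, 3)
        sigma_p = 0.4
        mix = category_predictive((1.0, -2.0), "S", D, DEFAULT_TYPE_SET, sigma_p)
        lls = np.array(
            [log_marginal(D, t.scales, sigma_p) for t in DEFAULT_TYPE_SET.stripy]
        )
        w = np.exp(lls - lls.max())
        assert mix.weights == pytest.approx(w / w.sum(), abs=1e-10)


class TestJensenEntropy:
    def test_single_component_closed_form(self):
        for var in (0.25, 1.0, 3.7):
            mix = GaussianMixture([1.0], [0.3], [var])
            assert jensen_entropy(mix) == pytest.approx(0.5 * np.log2(4 * np.pi * var), abs=1e-12)

    def test_two_identical_components_degenerate_to_one(self):
        one = GaussianMixture([1.0], [0.5], [1.2])
        two = GaussianMixture([0.4, 0.6], [0.5, 0.5], [1.2, 1.2])
        assert jensen_entropy(two) == pytest.approx(jensen_entropy(one), abs=1e-12)

    def test_lower_bounds_monte_carlo_entropy(self, rng):
        """The bound never exceeds an MC estimate of the true entropy (3 SE slack)."""
        for _ in range(10):
            k = rng.integers(1, 4)
            w = rng.dirichlet(np.ones(k))
            mu = rng.normal(0, 2, k)
            var = rng.uniform(0.1, 2.0, k)
            mix = GaussianMixture(w, mu, var)
            comp = rng.choice(k, size=50_000, p=w)
            x = rng.normal(mu[comp], np.sqrt(var[comp]))
            dens = (
                w
                * np.exp(-0.5 * (x[:, None] - mu) ** 2 / var)
                / np.sqrt(2 * np.pi * var)
            ).sum(axis=1)
            h = -np.log2(dens)
            mc, se = h.mean(), h.std(ddof=1) / np.sqrt(len(h))
            assert jensen_entropy(mix) <= mc + 3 * se

    def test_quadrature_entropy_matches_gaussian_closed_form(self):
        mix = GaussianMixture([1.0], [0.0], [2.0])
        assert mixture_entropy(mix) == pytest.approx(0.5 * np.log2(2 * np.pi * np.e * 2.0), abs=1e-9)


class TestScores:
    def test_empty_set_scores_zero_everywhere(self):
        params = ObserverParams(sigma_p=0.3)
        for pt in [(0.0, 0.0), (10.0, -10.0), (-13.0, 5.0)]:
            assert bas_score(pt, ObservationSet(), params, mode="exact") == pytest.approx(0.0, abs=1e-9)
            assert score_oracle(pt, ObservationSet(), params) == pytest.approx(0.0, abs=1e-9)

    def test_score_is_tiny_at_a_revealed_location(self, rng):
        params = ObserverParams(sigma_p=0.3)
        D = random_observations(rng, 4)
        for i in range(4):
            s = bas_score(D.locations[i], D, params, mode="exact")
            assert 0 <= s <= 1e-3

    def test_predictive_and_oracle_forms_agree(self, rng):
        """Eq-7-style and Eq-6-style exact scores are the same mutual information."""
        for _ in range(8):
            ts = random_type_set(rng)
            params = ObserverParams(sigma_p=rng.uniform(0.1, 1.0))
            D = random_observations(rng, rng.integers(1, 8))
            x_star = rng.uniform(-12, 12, 2)
            s7 = bas_score(x_star, D, params, ts, mode="exact")
            s6 = score_oracle(x_star, D, params, ts)
            assert s7 == pytest.approx(s6, abs=1e-6)

    def test_exact_score_bounded_by_category_entropy(self, rng):
        for _ in range(8):
            params = ObserverParams(sigma_p=rng.uniform(0.2, 0.8))
            D = random_observations(rng, rng.integers(1, 8))
            x_star = rng.uniform(-12, 12, 2)
            s = bas_score(x_star, D, params, mode="exact")
            h_cd = binary_entropy_bits(category_posterior(D, sigma_p=params.sigma_p).p_patchy)
            assert -1e-9 <= s <= h_cd + 1e-9

    def test_score_vanishes_far_from_all_observations(self, rng):
        params = ObserverParams(sigma_p=0.4)
        D = ObservationSet([(-13.0, -13.0), (-12.0, -13.0)], [1.0, -0.5])
        s = bas_score((13.9, 13.9), D, params, mode="exact")  # > 6 length scales away
        assert s <= 1e-4

    def test_jensen_score_tracks_exact_score(self, rng):
        """The Jensen default is an approximation but stays close to exact."""
        D = random_observations(rng, 5)
        params = ObserverParams(sigma_p=0.5)
        x_star = rng.uniform(-8, 8, 2)
        sj = bas_score(x_star, D, params)
        se = bas_score(x_star, D, params, mode="exact")
        assert sj == pytest.approx(se, abs=0.05)


class TestMaxEntropyScore:
    def test_empty_set_equals_prior_entropy_everywhere(self):
        params = ObserverParams(sigma_p=0.5)
        expected = 0.5 * np.log2(2 * np.pi * np.e * 1.25)
        for pt in [(0.0, 0.0), (-10.0, 3.0)]:
            assert max_entropy_score(pt, ObservationSet(), params, mode="exact") == pytest.approx(
                expected, abs=1e-9
            )

    def test_entropy_is_lower_at_a_revealed_location(self, obs_pair):
        params = ObserverParams(sigma_p=0.3)
        near = max_entropy_score((0.0, 0.0), obs_pair, params, mode="exact")
        far = max_entropy_score((10.0, 10.0), obs_pair, params, mode="exact")
        assert near < far

    def test_total_entropy_decomposes_into_score_plus_noise_entropy(self, rng):
        """H[z*|x*,D] = Score + sum_c P(c|D) H[z*|x*,c,D] on a shared quadrature."""
        D = random_observations(rng, 4)
        params = ObserverParams(sigma_p=0.4)
        x_star = (1.5, -2.0)
        from actsense.observer import biased_scales

        eff = biased_scales(DEFAULT_TYPE_SET, params.prior_bias)
        logml, means, variances = _type_components(x_star, D, eff, params.sigma_p)
        h_total, h_c, p_c, *_ = _score_terms_exact(logml, means, variances, eff)
        score = bas_score(x_star, D, params, mode="exact")
        noise = sum(p_c[c] * h_c[c] for c in ("P", "S"))
        assert h_total == pytest.approx(score + noise, abs=1e-9)
        assert max_entropy_score(x_star, D, params, mode="exact") == pytest.approx(h_total, abs=1e-9)


class TestChooseFixation:
    def test_empty_set_is_an_all_way_tie(self):
        params = ObserverParams(sigma_p=0.3)
        smap, loc1 = choose_fixation(
            ObservationSet(), params, score_kind="bas", rng=np.random.default_rng(1), mode="exact", grid_n=8
        )
        assert smap.scores.max() - smap.scores.min() <= 1e-9
        assert len(smap.argmax_locations()) == 64
        _, loc2 = choose_fixation(
            ObservationSet(), params, score_kind="bas", rng=np.random.default_rng(2), mode="exact", grid_n=8
        )
        assert not np.allclose(loc1, loc2)  # uniform tie-break over the grid

    def test_strong_observation_repels_the_next_fixation(self):
        params = ObserverParams(sigma_p=0.2)
        D = ObservationSet([(0.0, 0.0)], [2.5])
        smap, intended = choose_fixation(D, params, rng=np.random.default_rng(0))
        assert np.all(np.abs(intended) <= IMAGE_HALF_EXTENT)
        assert np.hypot(*intended) > 0.5  # not the revealed point

    def test_fixed_seed_reproduces_map_and_choice(self, obs_pair):
        params = ObserverParams(sigma_p=0.4)
        a = choose_fixation(obs_pair, params, rng=np.random.default_rng(9))
        b = choose_fixation(obs_pair, params, rng=np.random.default_rng(9))
        assert np.array_equal(a[0].scores, b[0].scores)
        assert np.array_equal(a[1], b[1])

    def test_greedy_selection_avoids_revealed_grid_points(self):
        """Inhibition of return emerges: exact-score BAS never refixates a sampled point."""
        img = sample_image("SH", rng=np.random.default_rng(3))
        params = ObserverParams(sigma_p=0.2)
        trial = simulate_trial(
            img, "bas", params, 10, np.random.default_rng(4), score_mode="exact", grid_n=16
        )
        intended = np.array([r.intended for r in trial.revealings])
        for i in range(1, len(intended)):
            dists = np.hypot(*(intended[:i] - intended[i]).T)
            assert dists.min() > 1e-9


class TestSaccadeNoise:
    def test_zero_model_is_exact(self, rng):
        out = apply_saccade_noise((0.0, 0.0), (5.0, -3.0), SaccadeNoiseModel.zero(), rng)
        assert out == pytest.approx([5.0, -3.0])

    def test_measured_tangential_sd_value(self):
        model = SaccadeNoiseModel.measured()
        assert model.sd_tan(5.56) == pytest.approx(0.13 * 5.56 + 0.41)
        assert model.sd_tan(5.56) == pytest.approx(1.1328)
        assert model.sd_orth(5.56) == pytest.approx(0.011 * 5.56 + 0.38)

    def test_undershoot_convention_is_switchable(self):
        under = SaccadeNoiseModel.measured(undershoot=True)
        over = SaccadeNoiseModel.measured(undershoot=False)
        assert under.bias(5.0) == pytest.approx(-(0.23 * 5 + 0.37))
        assert over.bias(5.0) == pytest.approx(0.23 * 5 + 0.37)

    def test_empirical_tangential_sd_matches_model(self):
        model = SaccadeNoiseModel.measured()
        rng = np.random.default_rng(0)
        start = np.zeros(2)
        intended = np.array([8.0, 0.0])
        xs = np.array(
            [apply_saccade_noise(start, intended, model, rng, clip=False) for _ in range(10_000)]
        )
        d = 8.0
        assert np.std(xs[:, 0]) == pytest.approx(model.sd_tan(d), rel=0.03)
        assert np.std(xs[:, 1]) == pytest.approx(model.sd_orth(d), rel=0.03)
        assert np.mean(xs[:, 0]) == pytest.approx(d + model.bias(d), abs=0.05)

    def test_executed_location_is_clipped_to_the_image(self):
        model = SaccadeNoiseModel.measured(undershoot=False)
        rng = np.random.default_rng(0)
        for _ in range(200):
            out = apply_saccade_noise((0.0, 0.0), (13.9, 13.9), model, rng)
            assert np.all(np.abs(out) <= IMAGE_HALF_EXTENT)
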