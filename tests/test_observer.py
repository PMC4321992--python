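import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from painbayes import (
    CueCondition,
    IntensityGrid,
    SubjectParams,
    build_cue_prior,
    build_prior,
    likelihood_kernel,
    map_estimate,
    posterior,
    prediction_surface,
    rating_distribution,
)
from painbayes.exceptions import DegeneratePosteriorError, InputError, ParameterError
from painbayes.observer import map_curve

from conftest import brute_force_mixture


# parameters used by the worked examples below (independent of the defaults)
EX_PARAMS = dict(sigma_prior=5.7, s_low=20.0, s_mid=50.0, s_high=80.0)


class TestPriors:
    def test_w_zero_collapses_to_uniform(self, grid):
        prior = build_prior(0.0, SubjectParams(w=0.0, **EX_PARAMS), grid)
        assert np.allclose(prior.mass, 1.0 / grid.n_points)

    def test_w_one_splits_mass_symmetrically(self):
        grid = IntensityGrid(0, 100, 1.0)
        p = SubjectParams(w=1.0, sigma_prior=5.0, s_low=20.0, s_mid=50.0, s_high=80.0)
        prior = build_prior(1.0, p, grid)
        below = prior.mass[grid.points < 50].sum()
        assert abs(below - 0.5) < 1e-6

    def test_matches_density_evaluation_oracle(self, grid):
        p = SubjectParams(w=0.9, **EX_PARAMS)
        prior = build_prior(0.9, p, grid)
        expected = brute_force_mixture(
            grid,
            [(0.45, 20.0, 5.7), (0.45, 80.0, 5.7)],
            uniform_weight=0.1,
        )
        assert np.allclose(prior.mass, expected, atol=1e-12)

    @pytest.mark.parametrize("w", [-0.1, 1.5])
    def test_invalid_weight_rejected(self, grid, w):
        with pytest.raises(ParameterError):
            build_prior(w, SubjectParams(w=0.5, **EX_PARAMS), grid)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ParameterError):
            SubjectParams(w=0.5, sigma_prior=-1.0)


class TestCuePriors:
    def test_no_cue_equals_plain_prior(self, grid):
        p = SubjectParams(w=0.7, **EX_PARAMS)
        assert np.array_equal(
            build_cue_prior("none", 0.7, p, grid).mass, build_prior(0.7, p, grid).mass
        )

    def test_green_full_weight_peaks_at_low_anchor(self, grid):
        p = SubjectParams(w=1.0, **EX_PARAMS)
        assert build_cue_prior("green", 1.0, p, grid).argmax_point() == 20.0

    def test_green_mixture_matches_oracle_within_two_sigma(self, grid):
        p = SubjectParams(w=0.5, sigma_prior=5.0, s_low=20.0, s_mid=50.0, s_high=80.0)
        prior = build_cue_prior("green", 0.5, p, grid)
        expected = brute_force_mixture(grid, [(0.5, 20.0, 5.0)], uniform_weight=0.5)
        window = (grid.points >= 10.0) & (grid.points <= 30.0)
        assert abs(prior.mass[window].sum() - expected[window].sum()) < 1e-12

    def test_unknown_cue_label_rejected(self, grid):
        with pytest.raises(InputError):
            build_cue_prior("blue-ish", 0.5, SubjectParams(w=0.5), grid)

    def test_cue_marginalization_recovers_no_cue_prior(self, grid):
        """Equiprobable red/green cues average back to the two-component mixture."""
        p = SubjectParams(w=0.8, **EX_PARAMS)
        avg = 0.5 * build_cue_prior("green", 0.8, p, grid).mass + 0.5 * build_cue_prior(
            "red", 0.8, p, grid
        ).mass
        assert np.allclose(avg, build_prior(0.8, p, grid).mass, atol=1e-12)


class TestLikelihoodKernel:
    def test_row_mode_on_diagonal(self, grid):
        kernel = likelihood_kernel(grid, sd=0.75)
        row = kernel.row(50.0)
        assert grid.points[np.argmax(row)] == 50.0

    def test_gaussian_ratio_at_one_sd(self):
        fine = IntensityGrid(0, 100, 0.05)
        kernel = likelihood_kernel(fine, sd=0.75)
        row = kernel.row(50.0)
        centre = row[fine.index_of(50.0)]
        ratio = row[fine.index_of(50.75)] / centre
        assert abs(ratio - np.exp(-0.5)) < 1e-3

    def test_every_row_normalized_including_edges(self, grid):
        kernel = likelihood_kernel(grid, sd=10.0)
        assert np.all(np.abs(kernel.matrix.sum(axis=1) - 1.0) < 1e-9)

    def test_nonpositive_sd_rejected(self, grid):
        with pytest.raises(ParameterError):
            likelihood_kernel(grid, sd=0.0)


class TestPosterior:
    def test_uniform_prior_gives_likelihood_mode(self, grid):
        p = SubjectParams(w=0.0, **EX_PARAMS)
        kernel = likelihood_kernel(grid, sd=p.sd_nociceptor)
        prior = build_prior(0.0, p, grid)
        for n in (13.0, 50.0, 87.5):
            assert map_estimate(posterior(prior, kernel, n)) == n

    def test_matches_brute_force_product_oracle(self, grid):
        p = SubjectParams(w=0.9, **EX_PARAMS)
        kernel = likelihood_kernel(grid, sd=p.sd_nociceptor)
        prior = build_cue_prior("green", 0.9, p, grid)
        post = posterior(prior, kernel, 80.0)
        # independent oracle: density evaluation of the mixture times the
        # Gaussian likelihood of the observation, renormalized
        prior_oracle = brute_force_mixture(grid, [(0.9, 20.0, 5.7)], uniform_weight=0.1)
        lik = norm.pdf(80.0, loc=grid.points, scale=p.sd_nociceptor)
        expected = prior_oracle * lik
        expected /= expected.sum()
        assert np.allclose(post.mass, expected, atol=1e-12)
        assert abs(post.mass.sum() - 1.0) < 1e-9

    def test_degenerate_posterior_raises(self):
        grid = IntensityGrid()
        p = SubjectParams(
            w=1.0, sigma_prior=2.0, sd_nociceptor=0.75, s_low=20.0, s_mid=30.0, s_high=40.0
        )
        kernel = likelihood_kernel(grid, sd=p.sd_nociceptor)
        prior = build_cue_prior("green", 1.0, p, grid)
        with pytest.raises(DegeneratePosteriorError):
            posterior(prior, kernel, 100.0)

    def test_rejection_sampling_oracle_total_variation(self, coarse_grid, rng):
        """Grid posterior agrees with a Monte-Carlo rejection sampler."""
        p = SubjectParams(w=0.8)
        kernel = likelihood_kernel(coarse_grid, sd=p.sd_nociceptor)
        prior = build_cue_prior("green", 0.8, p, coarse_grid)
        n_obs = 60.0
        post = posterior(prior, kernel, n_obs)

        draws = 10**6
        e = rng.choice(coarse_grid.points, size=draws, p=prior.mass)
        accept = rng.random(draws) < np.exp(
            -0.5 * ((n_obs - e) / p.sd_nociceptor) ** 2
        )
        kept = e[accept]
        counts = np.bincount(
            ((kept - coarse_grid.lo) / coarse_grid.step).astype(int),
            minlength=coarse_grid.n_points,
        )
        mc = counts / counts.sum()
        tv = 0.5 * np.abs(mc - post.mass).sum()
        assert tv < 0.02


class TestRatingDistribution:
    def test_unconditioned_mean_tracks_stimulus(self, grid):
        """With no learning the predicted rating is centred on the stimulus.

        Cross-checked against a Monte-Carlo simulation of the same
        generative chain (signal draw -> MAP -> rating noise).
        """
        p = SubjectParams(w=0.0)
        rng = np.random.default_rng(7)
        for s in (10.0, 30.0, 50.0, 70.0, 90.0):
            dist = rating_distribution(s, "none", p, grid)
            assert abs(dist.argmax_point() - s) <= grid.step
            # MC oracle of the same chain (flat prior => E-hat(n) = n); the
            # grid model renormalizes over the axis, i.e. conditions on the
            # range, so out-of-range draws are rejected rather than clipped
            n_draw = rng.normal(s, p.sd_nociceptor, 2 * 10**5)
            n_draw = np.round(n_draw[(n_draw >= 0) & (n_draw <= 100)] * 2) / 2
            r_draw = n_draw + rng.normal(0, p.sigma_rating, n_draw.size)
            r_draw = r_draw[(r_draw >= 0) & (r_draw <= 100)]
            assert r_draw.size > 10**5 // 2
            assert abs(dist.mean() - r_draw.mean()) < 0.3

    def test_symmetric_anchor_midpoint_is_balanced_bimodal(self, grid):
        """The midpoint prediction is bimodal and mirror-symmetric.

        Exact mass balance is broken only by the deterministic low-side tie
        break of the single signal column at exactly s_mid (whose posterior
        is perfectly symmetric), so the asymmetry is bounded by that
        column's signal weight.
        """
        from painbayes import gaussian_pmf

        p = SubjectParams(w=0.95)
        dist = rating_distribution(p.s_mid, "none", p, grid)
        assert len(dist.local_maxima()) == 2
        lo, hi = dist.local_maxima()
        assert abs((lo + hi) / 2 - p.s_mid) <= grid.step  # symmetric modes
        below = dist.mass[grid.points < p.s_mid].sum()
        above = dist.mass[grid.points > p.s_mid].sum()
        tied_weight = gaussian_pmf(grid, p.s_mid, p.sd_nociceptor)[grid.index_of(p.s_mid)]
        assert abs(below - above) <= tied_weight + 1e-9

    def test_green_cue_lowers_predicted_pain_at_high_stimulus(self, grid):
        p = SubjectParams(w=0.9)
        green = rating_distribution(p.s_high, "green", p, grid)
        red = rating_distribution(p.s_high, "red", p, grid)
        assert green.mean() < red.mean()

    def test_congruent_cue_sharpens_posterior(self, grid):
        """A cue consistent with the stimulus narrows the belief."""
        for w in (0.5, 0.7, 0.9):
            p = SubjectParams(w=w)
            kernel = likelihood_kernel(grid, sd=p.sd_nociceptor)
            with_cue = posterior(
                build_cue_prior("red", w, p, grid), kernel, p.s_high
            ).variance()
            without = posterior(
                build_cue_prior("none", w, p, grid), kernel, p.s_high
            ).variance()
            assert with_cue < without


class TestPredictionSurface:
    def test_rows_normalized_and_ridge_diagonal_without_learning(self, grid):
        surf = prediction_surface("none", SubjectParams(w=0.0), grid)
        assert np.all(np.abs(surf.matrix.sum(axis=1) - 1.0) < 1e-9)
        sel = (grid.points >= 10) & (grid.points <= 90)
        assert np.max(np.abs(surf.ridge[sel] - grid.points[sel])) <= grid.step

    def test_conditioned_ridge_has_plateaus_and_jump(self, grid):
        p = SubjectParams(w=0.9)
        surf = prediction_surface("none", p, grid)
        steps = np.diff(surf.ridge)
        assert np.all(steps >= -1e-9)  # non-decreasing
        jump = steps.max()
        assert jump > 10.0  # a macroscopic jump between the plateaus
        # plateaus near the two conditioned anchors
        mid_idx = grid.index_of(p.s_mid)
        assert abs(surf.ridge[mid_idx - 20] - p.s_low) < 5.0
        assert abs(surf.ridge[mid_idx + 20] - p.s_high) < 5.0

    def test_round_trips_through_dataframe(self, grid):
        surf = prediction_surface("green", SubjectParams(w=0.8), grid)
        frame = surf.to_frame()
        assert frame.shape == (grid.n_points, grid.n_points)
        assert np.allclose(frame.to_numpy().sum(axis=1), 1.0, atol=1e-9)


@settings(deadline=None, max_examples=30)
@given(
    w=st.floats(min_value=0.0, max_value=1.0),
    cue=st.sampled_from(["red", "green", "none"]),
    n=st.floats(min_value=0.0, max_value=100.0),
)
def test_posterior_always_normalized(w, cue, n):
    grid = IntensityGrid(0, 100, 1.0)
    p = SubjectParams(w=w)
    kernel = likelihood_kernel(grid, sd=p.sd_nociceptor)
    post = posterior(build_cue_prior(cue, w, p, grid), kernel, n)
    assert abs(post.mass.sum() - 1.0) < 1e-9
    assert grid.lo <= map_estimate(post) <= grid.hi


def test_map_curve_matches_pointwise_posteriors(grid):
    p = SubjectParams(w=0.85)
    kernel = likelihood_kernel(grid, sd=p.sd_nociceptor)
    prior = build_cue_prior("green", 0.85, p, grid)
    curve = map_curve(prior, kernel)
    for n in (0.0, 25.0, 50.0, 64.5, 100.0):
        assert curve[grid.index_of(n)] == map_estimate(posterior(prior, kernel, n))
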