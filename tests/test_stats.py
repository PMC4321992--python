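import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, norm, pearsonr, wilcoxon

from painbayes import (
    BeliefDistribution,
    IntensityGrid,
    bimodality_test,
    gaussian_pmf,
    kmeans2,
    mann_whitney_one_tailed,
    model_posteriors,
    pearson_one_tailed,
    rank_tests,
    signed_rank_one_tailed,
)
from painbayes.exceptions import (
    DegenerateClusteringError,
    InputError,
    UndefinedCorrelationError,
    UndefinedTestError,
)


@pytest.fixture(scope="module")
def small_grid():
    return IntensityGrid(0, 100, 1.0)


class TestModelPosteriors:
    def test_identical_predictives_split_evenly(self, small_grid):
        pred = BeliefDistribution(small_grid, gaussian_pmf(small_grid, 50, 10))
        scores = model_posteriors([40.0, 55.0], {"a": pred, "b": pred})
        assert all(s.posterior == pytest.approx(0.5) for s in scores)
        assert all(s.bayes_factor_vs_best_alt == pytest.approx(1.0) for s in scores)

    def test_posteriors_sum_to_one_over_three_models(self, small_grid):
        preds = {
            name: BeliefDistribution(small_grid, gaussian_pmf(small_grid, mu, sd))
            for name, (mu, sd) in {"a": (40, 8), "b": (60, 8), "c": (50, 20)}.items()
        }
        scores = model_posteriors([45.0, 52.0, 58.0], preds)
        assert sum(s.posterior for s in scores) == pytest.approx(1.0, abs=1e-9)

    def test_better_matching_model_wins(self, small_grid):
        preds = {
            "near": BeliefDistribution(small_grid, gaussian_pmf(small_grid, 50, 5)),
            "far": BeliefDistribution(small_grid, gaussian_pmf(small_grid, 20, 5)),
        }
        scores = {s.model: s for s in model_posteriors([48.0, 51.0, 53.0], preds)}
        assert scores["near"].posterior > 0.99
        assert scores["near"].bayes_factor_vs_best_alt > 1.0

    def test_out_of_grid_rating_clamped_with_warning(self, small_grid):
        pred = BeliefDistribution(small_grid, gaussian_pmf(small_grid, 90, 10))
        with pytest.warns(UserWarning, match="clamped"):
            scores = model_posteriors([120.0], {"a": pred, "b": pred})
        assert np.isfinite(scores[0].loglik)

    def test_zero_mass_observation_flags_model(self, small_grid):
        mass = np.zeros(small_grid.n_points)
        mass[:10] = 0.1
        spiky = BeliefDistribution(small_grid, mass)
        broad = BeliefDistribution(small_grid, gaussian_pmf(small_grid, 50, 20))
        scores = {s.model: s for s in model_posteriors([50.0], {"s": spiky, "b": broad})}
        assert scores["s"].flagged and scores["s"].posterior == 0.0


def _brute_force_best_2partition(x):
    """Exhaustive minimum within-SS over all 2-partitions (oracle)."""
    n = len(x)
    best = math.inf
    for mask in range(1, 2 ** n - 1):
        a = [x[i] for i in range(n) if mask >> i & 1]
        b = [x[i] for i in range(n) if not mask >> i & 1]
        ss = sum((v - np.mean(a)) ** 2 for v in a) + sum((v - np.mean(b)) ** 2 for v in b)
        best = min(best, ss)
    return best


class TestKmeans2:
    def test_perfectly_separated_pairs(self):
        res = kmeans2([0.0, 0.0, 10.0, 10.0])
        assert res.centers == (0.0, 10.0)
        assert res.center_distance == 10.0
        assert res.separation_index == pytest.approx(1.0)

    def test_textbook_arithmetic_case(self):
        res = kmeans2([0.0, 2.0, 8.0, 10.0])
        assert res.centers == (1.0, 9.0)
        assert res.within_ss == pytest.approx(4.0)
        assert res.total_ss == pytest.approx(68.0)
        assert res.separation_index == pytest.approx(64.0 / 68.0)
        assert res.sizes == (2, 2)

    def test_matches_brute_force_on_random_mixtures(self, rng):
        for _ in range(20):
            x = np.concatenate(
                [rng.normal(30, 6, rng.integers(2, 5)), rng.normal(70, 6, rng.integers(2, 5))]
            )
            res = kmeans2(x)
            assert res.within_ss == pytest.approx(_brute_force_best_2partition(list(x)))

    def test_matches_brute_force_on_unstructured_data(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 100, 9)
            assert kmeans2(x).within_ss == pytest.approx(
                _brute_force_best_2partition(list(x))
            )

    def test_all_equal_scores_rejected(self):
        with pytest.raises(DegenerateClusteringError):
            kmeans2([5.0, 5.0, 5.0])
        with pytest.raises(InputError):
            kmeans2([5.0])

    @settings(deadline=None, max_examples=40)
    @given(
        x=st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False), min_size=2, max_size=12
        )
    )
    def test_separation_index_bounds(self, x):
        if len(set(x)) < 2:
            return
        try:
            res = kmeans2(x)
        except DegenerateClusteringError:
            return  # squared deviations underflowed; clustering undefined
        assert -1e-12 <= res.separation_index <= 1.0 + 1e-12
        if res.within_ss < 1e-12:
            assert res.separation_index == pytest.approx(1.0)


class TestBimodality:
    def test_well_separated_clusters_favour_bimodality(self):
        x = [28.0, 30.0, 31.0, 33.0, 98.0, 100.0, 101.0, 103.0]
        res = bimodality_test(x)
        assert res.posterior_prob_bimodal > 0.5
        assert res.bayes_factor > 1.0

    def test_matches_arithmetic_oracle(self):
        """Posterior equals the two-likelihood arithmetic computed independently."""
        x = np.array([30.0, 32.0, 35.0, 37.0, 90.0, 92.0, 95.0, 99.0])
        res = bimodality_test(x)
        # oracle: same hypotheses built directly with scipy
        cl = kmeans2(x)
        log_uni = norm.logpdf(x, x.mean(), x.std(ddof=1)).sum()
        comps = []
        for k in (0, 1):
            m = x[cl.assignments == k]
            comps.append((m.size / x.size, m.mean(), max(m.std(ddof=1), 0.5)))
        mix = sum(w * norm.pdf(x, mu, sd) for w, mu, sd in comps)
        log_bi = np.log(mix).sum()
        bf = math.exp(log_bi - log_uni)
        assert res.bayes_factor == pytest.approx(bf, rel=1e-9)
        assert res.posterior_prob_bimodal == pytest.approx(bf / (1 + bf), rel=1e-9)

    def test_posterior_approaches_one_with_separation(self, rng):
        spread = rng.normal(0, 3, 8)
        posts = []
        for gap in (10.0, 40.0, 160.0):
            x = np.concatenate([spread[:4], spread[4:] + gap]) + 200
            posts.append(bimodality_test(x).posterior_prob_bimodal)
        assert posts == sorted(posts)
        assert posts[-1] > 0.999

    def test_tight_cluster_triggers_sd_floor_warning(self):
        x = [10.0, 10.0, 10.0, 10.0, 50.0, 50.0, 50.0, 50.1]
        with pytest.warns(UserWarning, match="floor"):
            res = bimodality_test(x)
        assert res.sd_floored

    def test_needs_at_least_four_scores(self):
        with pytest.raises(InputError):
            bimodality_test([1.0, 2.0, 3.0])


class TestPearson:
    def test_perfect_positive_line(self):
        res = pearson_one_tailed([1, 2, 3, 4], [3, 5, 7, 9])
        assert res["r"] == pytest.approx(1.0)
        assert res["P"] == 0.0

    def test_negative_slope_has_large_one_tailed_p(self):
        res = pearson_one_tailed([1, 2, 3, 4], [4, 3, 2, 1])
        assert res["r"] == pytest.approx(-1.0)
        assert res["P"] > 0.5

    def test_matches_reference_formula_to_1e10(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0])
        res = pearson_one_tailed(x, y)
        ref = pearsonr(x, y, alternative="greater")
        assert res["r"] == pytest.approx(ref.statistic, abs=1e-10)
        assert res["P"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_one_tailed([1, 1, 1], [1, 2, 3])


class TestRankTests:
    def test_identical_paired_samples_undefined(self):
        with pytest.raises(UndefinedTestError):
            rank_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)

    def test_extreme_rank_split_gives_one_over_twenty(self):
        res = mann_whitney_one_tailed([1, 2, 3], [4, 5, 6], alternative="less")
        assert res["P_one_tailed"] == pytest.approx(1 / 20)

    def test_mann_whitney_matches_scipy_exact_without_ties(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 7)
            mine = mann_whitney_one_tailed(a, b, alternative="greater")
            ref = mannwhitneyu(a, b, alternative="greater", method="exact")
            assert mine["P_one_tailed"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_signed_rank_matches_full_sign_enumeration(self, rng):
        d = np.array([1.5, -0.5, 2.0, -2.5, 3.0, 0.75])
        mine = signed_rank_one_tailed(d, alternative="greater")
        # independent oracle: enumerate all 2^6 sign patterns explicitly
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        count = sum(
            sum(r for r, s in zip(ranks, signs) if s) >= w_obs - 1e-9
            for signs in itertools.product((0, 1), repeat=6)
        )
        assert mine["P_one_tailed"] == pytest.approx(count / 64)
        ref = wilcoxon(d, alternative="greater", method="exact")
        assert mine["P_one_tailed"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_handles_ties_via_midranks(self):
        # tied observations across groups: enumeration stays valid
        res = mann_whitney_one_tailed([1.0, 2.0, 2.0], [2.0, 3.0, 4.0], alternative="less")
        assert 0.0 < res["P_one_tailed"] <= 0.5

    def test_normal_approximation_close_to_exact_at_moderate_n(self, rng):
        a = rng.normal(0.8, 1, 12)
        b = rng.normal(0.0, 1, 12)
        approx = mann_whitney_one_tailed(a, b, alternative="greater", exact_limit=10)
        exact = mann_whitney_one_tailed(a, b, alternative="greater", exact_limit=12)
        assert approx["P_one_tailed"] == pytest.approx(exact["P_one_tailed"], abs=0.02)

    def test_direction_argument_flips_tail(self):
        a, b = [5, 6, 7], [1, 2, 3]
        high = rank_tests(a, b, paired=False, alternative="greater")["P_one_tailed"]
        low = rank_tests(a, b, paired=False, alternative="less")["P_one_tailed"]
        assert high < 0.1 < low
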