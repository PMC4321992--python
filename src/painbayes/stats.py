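"""Model comparison, clustering, bimodality and rank statistics.

Bayesian model comparison scores each candidate model by the predictive
likelihood of held-out ratings (the uncued mixed-intensity block), converts
the scores to posterior probabilities under equal model priors, and reports
Bayes factors against the best alternative.

Clustering of a subject's mid-stimulus ratings uses the Hartigan-Wong
k-means algorithm with k = 2 and deterministic quantile-pair restarts; the
separation index is (total SS - within SS) / total SS. The bimodality test
compares plug-in likelihoods of a single Gaussian (moments of all scores)
against a two-Gaussian mixture built from the k-means clusters, with equal
hypothesis priors.

Rank tests (Wilcoxon signed-rank and Mann-Whitney rank-sum) are one-tailed
and exact — full enumeration of sign patterns or rank splits, valid under
ties — for small samples, with a tie-corrected normal approximation beyond.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    DegenerateClusteringError,
    InputError,
    UndefinedCorrelationError,
    UndefinedTestError,
)
from .grid import BeliefDistribution

__all__ = [
    "ModelScore",
    "model_posteriors",
    "ClusterSummary",
    "kmeans2",
    "BimodalityResult",
    "bimodality_test",
    "pearson_one_tailed",
    "rank_tests",
    "mann_whitney_one_tailed",
    "signed_rank_one_tailed",
]


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelScore:
    model: str
    loglik: float
    posterior: float
    bayes_factor_vs_best_alt: float
    flagged: bool = False  # a held-out rating had zero predictive mass


def model_posteriors(
    ratings: Sequence[float],
    predictives: Mapping[str, BeliefDistribution],
) -> list[ModelScore]:
    """Score competing models on held-out ratings under equal priors.

    Ratings outside the grid range are clamped to the boundary with a
    warning; a model assigning zero mass to any rating receives -inf
    log-likelihood (hence minimal posterior) and is flagged.
    """
    if not predictives:
        raise InputError("no predictive distributions supplied")
    ratings = np.asarray(list(ratings), dtype=float)
    if ratings.size == 0:
        raise InputError("no held-out ratings supplied")
    grids = {p.grid for p in predictives.values()}
    if len(grids) != 1:
        raise InputError("all predictives must share one grid")
    grid = grids.pop()
    clamped = np.clip(ratings, grid.lo, grid.hi)
    if np.any(clamped != ratings):
        warnings.warn("held-out ratings outside the grid were clamped to the boundary")

    names = list(predictives)
    logliks = np.array(
        [float(predictives[name].log_mass_at(clamped).sum()) for name in names]
    )
    finite = np.isfinite(logliks)
    if not np.any(finite):
        raise InputError("every model assigns zero mass to the held-out data")
    shifted = logliks - logliks[finite].max()
    weights = np.where(np.isfinite(shifted), np.exp(shifted), 0.0)
    posteriors = weights / weights.sum()

    scores = []
    for i, name in enumerate(names):
        others = np.delete(logliks, i)
        best_alt = others.max()
        if np.isfinite(logliks[i]) and np.isfinite(best_alt):
            bf = float(np.exp(logliks[i] - best_alt))
        elif np.isfinite(logliks[i]):
            bf = float("inf")
        else:
            bf = 0.0
        scores.append(
            ModelScore(
                model=name,
                loglik=float(logliks[i]),
                posterior=float(posteriors[i]),
                bayes_factor_vs_best_alt=bf,
                flagged=not np.isfinite(logliks[i]),
            )
        )
    return scores


# ---------------------------------------------------------------------------
# Hartigan-Wong k-means, k = 2
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSummary:
    centers: tuple[float, float]  # sorted ascending
    assignments: np.ndarray = field(repr=False)  # 0 = lower-center cluster
    center_distance: float = 0.0
    within_ss: float = 0.0
    total_ss: float = 0.0
    separation_index: float = 0.0
    sizes: tuple[int, int] = (0, 0)


def _best_sorted_split(x: np.ndarray) -> np.ndarray:
    """Optimal two-cluster assignment of a scalar sample.

    For one-dimensional data the minimum within-SS two-partition is a
    contiguous split of the sorted sample, so scanning the n-1 splits (via
    prefix sums) is an exhaustive restart scheme that attains the global
    optimum deterministically.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    sizes = np.arange(1, n)
    left = csq[:-1] - csum[:-1] ** 2 / sizes
    right = (csq[-1] - csq[:-1]) - (csum[-1] - csum[:-1]) ** 2 / (n - sizes)
    k = int(np.argmin(left + right)) + 1
    assign = np.empty(n, dtype=int)
    assign[order[:k]] = 0
    assign[order[k:]] = 1
    return assign


def _hartigan_wong_refine(x: np.ndarray, assign: np.ndarray) -> tuple[np.ndarray, float]:
    """Hartigan-Wong transfer stage for k=2.

    Applies the size-corrected within-SS transfer criterion until no
    single-point move improves the objective (a no-op when the assignment is
    already globally optimal).
    """
    n = x.size
    assign = assign.copy()
    for _ in range(200):
        moved = False
        for i in range(n):
            a = assign[i]
            b = 1 - a
            na = int(np.sum(assign == a))
            nb = n - na
            if na <= 1:
                continue
            ca = x[assign == a].mean()
            cb = x[assign == b].mean() if nb else 0.0
            gain_remove = na / (na - 1) * (x[i] - ca) ** 2
            cost_add = nb / (nb + 1) * (x[i] - cb) ** 2
            if cost_add < gain_remove - 1e-12:
                assign[i] = b
                moved = True
        if not moved:
            break
    within = sum(
        float(((x[assign == k] - x[assign == k].mean()) ** 2).sum()) for k in (0, 1)
    )
    return assign, within


def kmeans2(scores: Sequence[float], seed: int = 0) -> ClusterSummary:
    """Two-cluster k-means (Hartigan-Wong) on a scalar sample.

    The exhaustive sorted-split scan provides the deterministic restarts —
    for scalar data it covers every candidate optimum, so the solution
    always equals the brute-force best two-partition — and the
    Hartigan-Wong transfer stage confirms convergence. ``seed`` is accepted
    for interface stability; the procedure is deterministic regardless.
    """
    x = np.asarray(list(scores), dtype=float)
    if x.size < 2:
        raise InputError("clustering needs at least two scores")
    total = float(((x - x.mean()) ** 2).sum())
    if np.ptp(x) == 0 or total == 0.0:
        raise DegenerateClusteringError("all scores (numerically) identical; two clusters undefined")

    assign, within = _hartigan_wong_refine(x, _best_sorted_split(x))

    m0, m1 = x[assign == 0].mean(), x[assign == 1].mean()
    if m0 > m1:
        assign = 1 - assign
        m0, m1 = m1, m0
    separation = (total - within) / total
    return ClusterSummary(
        centers=(float(m0), float(m1)),
        assignments=assign,
        center_distance=float(m1 - m0),
        within_ss=float(within),
        total_ss=total,
        separation_index=float(separation),
        sizes=(int(np.sum(assign == 0)), int(np.sum(assign == 1))),
    )


# ---------------------------------------------------------------------------
# bimodality test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BimodalityResult:
    posterior_prob_bimodal: float
    bayes_factor: float
    degenerate: bool = False
    sd_floored: bool = False
    clusters: ClusterSummary | None = None


#: scaled-VAS floor applied to degenerate (near-zero spread) cluster s.d.s
SD_FLOOR = 0.5


def _log_normal_pdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mean) / sd) ** 2 - math.log(sd * math.sqrt(2 * math.pi))


def bimodality_test(scores: Sequence[float], seed: int = 0) -> BimodalityResult:
    """Bayesian comparison of a bimodal vs a unimodal rating distribution.

    Both hypotheses are built from the data (plug-in parameters): the
    unimodal density is a Gaussian with the overall mean and s.d.; the
    bimodal density is a two-Gaussian mixture with the means and s.d.s of
    the two Hartigan-Wong clusters and weights proportional to cluster
    sizes. With equal hypothesis priors the posterior probability of
    bimodality is BF / (1 + BF), BF the likelihood ratio.
    """
    x = np.asarray(list(scores), dtype=float)
    if x.size < 4:
        raise InputError("bimodality test needs at least four scores")
    clusters = kmeans2(x, seed=seed)

    degenerate = min(clusters.sizes) < 2
    sd_all = float(x.std(ddof=1))
    floored = False
    comp_params = []
    for k in (0, 1):
        members = x[clusters.assignments == k]
        sd_k = float(members.std(ddof=1)) if members.size >= 2 else 0.0
        if sd_k < SD_FLOOR:
            sd_k = SD_FLOOR
            floored = True
            warnings.warn(f"cluster {k} s.d. below floor; using {SD_FLOOR}")
        comp_params.append((float(members.mean()), sd_k, members.size / x.size))

    log_l_uni = float(_log_normal_pdf(x, float(x.mean()), max(sd_all, SD_FLOOR)).sum())
    comp_logs = np.stack(
        [np.log(wk) + _log_normal_pdf(x, mk, sk) for (mk, sk, wk) in comp_params]
    )
    log_l_bi = float(np.logaddexp(comp_logs[0], comp_logs[1]).sum())

    log_bf = log_l_bi - log_l_uni
    bf = float(np.exp(log_bf)) if log_bf < 700 else float("inf")
    posterior = 1.0 / (1.0 + math.exp(-log_bf)) if abs(log_bf) < 700 else float(log_bf > 0)
    return BimodalityResult(
        posterior_prob_bimodal=posterior,
        bayes_factor=bf,
        degenerate=degenerate,
        sd_floored=floored,
        clusters=clusters,
    )


# ---------------------------------------------------------------------------
# correlation and rank tests
# ---------------------------------------------------------------------------

def pearson_one_tailed(x, y, alternative: str = "greater") -> dict:
    """Pearson product-moment correlation with a one-tailed P value.

    P is computed from the exact t transform ``t = r sqrt(n-2) / sqrt(1-r^2)``
    with n - 2 degrees of freedom; ``alternative`` is the direction of the
    alternative hypothesis ("greater": r > 0).
    """
    from scipy import stats as sps

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need equal-length vectors with at least 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    if alternative not in ("greater", "less"):
        raise InputError(f"unknown alternative {alternative!r}")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        p_greater = 0.0 if r > 0 else 1.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p_greater = float(sps.t.sf(t, df=n - 2))
    p = p_greater if alternative == "greater" else 1.0 - p_greater
    return {"r": r, "P": p}


def _midranks(values: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(values)


def mann_whitney_one_tailed(
    a, b, alternative: str = "greater", exact_limit: int = 10
) -> dict:
    """One-tailed Mann-Whitney rank-sum test.

    ``alternative="greater"`` tests H1: a tends to exceed b. Exact P by full
    enumeration of rank splits (valid under ties) when both groups have at
    most ``exact_limit`` observations; tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 1 or b.size < 1:
        raise InputError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise InputError(f"unknown alternative {alternative!r}")
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    w_obs = float(ranks[: a.size].sum())
    n1, n2 = a.size, b.size

    if max(n1, n2) <= exact_limit:
        idx = range(n1 + n2)
        count = 0
        total = 0
        for subset in itertools.combinations(idx, n1):
            w = float(ranks[list(subset)].sum())
            total += 1
            if alternative == "greater":
                count += w >= w_obs - 1e-9
            else:
                count += w <= w_obs + 1e-9
        p = count / total
    else:
        mean_w = n1 * (n1 + n2 + 1) / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var_w = n1 * n2 / 12.0 * ((n1 + n2 + 1) - tie_term / ((n1 + n2) * (n1 + n2 - 1)))
        if var_w <= 0:
            raise UndefinedTestError("all observations tied; rank-sum test undefined")
        from scipy import stats as sps

        z = (w_obs - mean_w) / math.sqrt(var_w)
        p = float(sps.norm.sf(z)) if alternative == "greater" else float(sps.norm.cdf(z))
    return {"statistic": w_obs, "P_one_tailed": float(p)}


def signed_rank_one_tailed(
    a, b=None, alternative: str = "greater", exact_limit: int = 12
) -> dict:
    """One-tailed Wilcoxon signed-rank test for paired samples.

    Tests H1: a tends to exceed b (``alternative="greater"``). Zero
    differences are discarded; if all differences are zero the test is
    undefined. Exact P enumerates all sign patterns (valid under tied
    magnitudes) up to ``exact_limit`` non-zero pairs; beyond that a
    tie-corrected normal approximation is used.
    """
    a = np.asarray(list(a), dtype=float)
    if b is None:
        d = a
    else:
        b = np.asarray(list(b), dtype=float)
        if a.size != b.size:
            raise InputError("paired samples must have equal length")
        d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedTestError("all paired differences are zero")
    if alternative not in ("greater", "less"):
        raise InputError(f"unknown alternative {alternative!r}")
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    n = d.size

    if n <= exact_limit:
        count = 0
        total = 2**n
        for signs in itertools.product((0, 1), repeat=n):
            w = float(sum(r for r, s in zip(ranks, signs) if s))
            if alternative == "greater":
                count += w >= w_pos - 1e-9
            else:
                count += w <= w_pos + 1e-9
        p = count / total
    else:
        mean_w = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var_w <= 0:
            raise UndefinedTestError("signed-rank variance is zero")
        from scipy import stats as sps

        z = (w_pos - mean_w) / math.sqrt(var_w)
        p = float(sps.norm.sf(z)) if alternative == "greater" else float(sps.norm.cdf(z))
    return {"statistic": w_pos, "P_one_tailed": float(p)}


def rank_tests(sample_a, sample_b, paired: bool, alternative: str = "greater") -> dict:
    """Dispatch to the paired (signed-rank) or unpaired (rank-sum) test."""
    if paired:
        return signed_rank_one_tailed(sample_a, sample_b, alternative=alternative)
    return mann_whitney_one_tailed(sample_a, sample_b, alternative=alternative)
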