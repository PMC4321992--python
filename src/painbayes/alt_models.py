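"""Competitor models of the post-conditioning rating distribution.

Two alternatives to the full Bayesian decision observer, both built directly
from a subject's conditioning-block rating summaries:

* the *no-learn* model — conditioning leaves perception untouched, so the
  rating for any stimulus is a unimodal Gaussian whose mean interpolates
  linearly between the low- and high-stimulus conditioning means;
* the *simple Bayesian* model — the expectation acquired in conditioning
  (an equal-weight two-Gaussian prior, no uniform floor and no expectation
  weight) is combined with the stimulus likelihood in a single Bayes step,
  and the resulting posterior is read out directly as the predicted rating
  distribution, with no decision or rating-noise stage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import InputError, ParameterError
from .grid import (
    BeliefDistribution,
    IntensityGrid,
    gaussian_pmf,
)
from .observer import CueCondition, SubjectParams

logger = logging.getLogger(__name__)

__all__ = ["ConditioningStats", "no_learn_predictive", "simple_bayes_predictive"]


@dataclass(frozen=True)
class ConditioningStats:
    """Per-subject summary of conditioning-block ratings.

    Means and standard deviations of the ratings given to low and high
    stimuli during the training blocks, on whichever rating scale the caller
    is working in (raw or scaled VAS).
    """

    mean_low: float
    sd_low: float
    mean_high: float
    sd_high: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.mean_low, self.sd_low, self.mean_high, self.sd_high])):
            raise InputError("conditioning statistics must be finite")
        if self.mean_low >= self.mean_high:
            # expected for a conditioned subject, but a noisy small sample can
            # violate it; log rather than refuse
            logger.warning(
                "conditioning means not ordered: mean_low=%.3f >= mean_high=%.3f",
                self.mean_low,
                self.mean_high,
            )

    @property
    def pooled_sd(self) -> float:
        """Root-mean-square of the two conditioning standard deviations."""
        return float(np.sqrt((self.sd_low**2 + self.sd_high**2) / 2.0))

    @classmethod
    def from_ratings(cls, low, high) -> "ConditioningStats":
        low = np.asarray(low, dtype=float)
        high = np.asarray(high, dtype=float)
        if low.size < 2 or high.size < 2:
            raise InputError("need at least two conditioning ratings per stimulus level")
        return cls(
            mean_low=float(low.mean()),
            sd_low=float(low.std(ddof=1)),
            mean_high=float(high.mean()),
            sd_high=float(high.std(ddof=1)),
        )

    def _require_positive_sds(self) -> None:
        if self.sd_low <= 0 or self.sd_high <= 0:
            raise ParameterError(
                f"degenerate conditioning s.d. (sd_low={self.sd_low}, sd_high={self.sd_high})"
            )


def no_learn_predictive(
    stats: ConditioningStats,
    s: float,
    grid: IntensityGrid,
    *,
    s_low: float,
    s_high: float,
) -> BeliefDistribution:
    """Unimodal Gaussian predictive of the no-learn model.

    The mean interpolates linearly between the conditioning means according
    to the position of the stimulus ``s`` between the anchors, so the mid
    stimulus maps to the exact midpoint of the reported pain levels. The
    spread is the pooled conditioning standard deviation.
    """
    stats._require_positive_sds()
    if s_high <= s_low:
        raise ParameterError(f"anchors must satisfy s_low < s_high, got ({s_low}, {s_high})")
    frac = (s - s_low) / (s_high - s_low)
    mean = stats.mean_low + frac * (stats.mean_high - stats.mean_low)
    return BeliefDistribution(grid, gaussian_pmf(grid, mean, stats.pooled_sd))


def simple_bayes_predictive(
    stats: ConditioningStats,
    s: float,
    cue: CueCondition | str,
    params: SubjectParams,
    grid: IntensityGrid,
    *,
    cue_conditioning: bool = False,
) -> BeliefDistribution:
    """Posterior of the simple Bayesian model, read out as the predictive.

    The prior is the equal-weight mixture of the two conditioning Gaussians
    (components discretized and renormalized on the grid); the likelihood is
    the untruncated Gaussian density of the stimulus with the nociceptor
    width ``params.sd_nociceptor``. By default the cue is ignored — the model
    has no cue-learning stage; ``cue_conditioning=True`` lets a colored cue
    select its associated component instead.
    """
    stats._require_positive_sds()
    cue = CueCondition.coerce(cue)
    if cue_conditioning and cue is CueCondition.GREEN:
        prior = gaussian_pmf(grid, stats.mean_low, stats.sd_low)
    elif cue_conditioning and cue is CueCondition.RED:
        prior = gaussian_pmf(grid, stats.mean_high, stats.sd_high)
    else:
        prior = 0.5 * gaussian_pmf(grid, stats.mean_low, stats.sd_low) + 0.5 * gaussian_pmf(
            grid, stats.mean_high, stats.sd_high
        )
    z = (grid.points - s) / params.sd_nociceptor
    likelihood = np.exp(-0.5 * z * z)
    return BeliefDistribution.from_unnormalized(grid, prior * likelihood)
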