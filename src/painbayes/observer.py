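"""The full Bayesian decision (fBD) observer.

The observer treats pain perception as a two-stage process. *Inference*:
combine a conditioned prior over the stimulus effect E with the Gaussian
nociceptor likelihood Pr(N|E) — and, when a symbolic cue C is present, with
the cue-conditioned prior Pr(E|C) — to obtain the posterior Pr(E|N,C).
*Decision*: under a uniform cost function the optimal point estimate is the
posterior mode (MAP), the perceived intensity E-hat. Reported ratings add
Gaussian coding noise around E-hat, so the predicted rating distribution
Pr(R|S,C) marginalizes the whole chain over the nociceptor signal N given
the delivered stimulus S.

Conditioning with two stimulus intensities in equal proportion leaves the
prior

    Pr(E) = w/2 N(s_low, sigma) + w/2 N(s_high, sigma) + (1 - w) Uniform,

where w in [0, 1] measures the effectiveness of conditioning/expectation and
the uniform floor keeps every intensity possible. A cue disambiguates which
conditioned stimulus to expect: it selects its associated component with
total weight w while keeping the (1 - w) uniform floor.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .exceptions import DegeneratePosteriorError, InputError, ParameterError
from .grid import (
    BeliefDistribution,
    IntensityGrid,
    LikelihoodKernel,
    gaussian_density_matrix,
    gaussian_pmf,
    likelihood_kernel,
)

__all__ = [
    "CueCondition",
    "SubjectParams",
    "build_prior",
    "build_cue_prior",
    "likelihood_kernel",
    "posterior",
    "map_estimate",
    "map_curve",
    "rating_distribution",
    "PredictionSurface",
    "prediction_surface",
]


class CueCondition(str, enum.Enum):
    """Symbolic cue paired with a stimulus.

    The training design fixes the associations: red signalled the high
    conditioning intensity, green the low one. ``NONE`` covers both the
    neutral blue cue of the no-cue test block and genuinely uncued trials.
    """

    RED = "red"
    GREEN = "green"
    NONE = "none"

    @classmethod
    def coerce(cls, value: "CueCondition | str") -> "CueCondition":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise InputError(
                f"unknown cue {value!r}; expected one of {[c.value for c in cls]}"
            ) from None


@dataclass(frozen=True)
class SubjectParams:
    """Generative and inference parameters of one subject.

    Parameters
    ----------
    w : float
        Expectation/conditioning weight in [0, 1]; 1 - w is the weight of the
        uniform "anything possible" prior component.
    sigma_prior : float
        Standard deviation of the conditioned prior components (intensity
        units). Default 5.7, the cohort-mean estimate from the conditioning
        experiment.
    sd_nociceptor : float
        Width of the sensory likelihood Pr(N|E) (and of Pr(N|S)) expressed on
        the intensity axis. Electrophysiological reports put this dispersion
        at 0.75 in normalized nociceptor-response units; the gain linking the
        response scale to the 0-100 intensity axis is not fixed by those
        reports, and the default of 10.0 intensity units places the observer
        in the regime where conditioning visibly modulates perception.
    sigma_rating : float
        Width of the rating (coding) noise Pr(R|E-hat), intensity units.
    s_low, s_mid, s_high : float
        Stimulus anchor intensities; the mid anchor sits at the midpoint of
        the low and high anchors in the two-level conditioning design.
    """

    w: float
    sigma_prior: float = 5.7
    sd_nociceptor: float = 10.0
    sigma_rating: float = 4.0
    s_low: float = 35.0
    s_mid: float = 50.0
    s_high: float = 65.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ParameterError(f"w must lie in [0, 1], got {self.w}")
        for name in ("sigma_prior", "sd_nociceptor", "sigma_rating"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if not self.s_low < self.s_mid < self.s_high:
            raise ParameterError(
                f"anchors must satisfy s_low < s_mid < s_high, got "
                f"({self.s_low}, {self.s_mid}, {self.s_high})"
            )

    def with_w(self, w: float) -> "SubjectParams":
        return replace(self, w=w)

    def anchor(self, level: str) -> float:
        try:
            return {"low": self.s_low, "mid": self.s_mid, "high": self.s_high}[level]
        except KeyError:
            raise InputError(f"unknown stimulus level {level!r}") from None


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def build_prior(w: float, params: SubjectParams, grid: IntensityGrid) -> BeliefDistribution:
    """No-cue prior after conditioning: two Gaussians plus a uniform floor."""
    if not 0.0 <= w <= 1.0:
        raise ParameterError(f"w must lie in [0, 1], got {w}")
    if params.sigma_prior <= 0:
        raise ParameterError("sigma_prior must be positive")
    uniform = np.full(grid.n_points, 1.0 / grid.n_points)
    mass = (1.0 - w) * uniform
    if w > 0:
        mass = mass + (w / 2.0) * gaussian_pmf(grid, params.s_low, params.sigma_prior)
        mass = mass + (w / 2.0) * gaussian_pmf(grid, params.s_high, params.sigma_prior)
    return BeliefDistribution(grid, mass)


def build_cue_prior(
    cue: CueCondition | str, w: float, params: SubjectParams, grid: IntensityGrid
) -> BeliefDistribution:
    """Cue-conditioned prior Pr(E|C).

    The cue selects its associated conditioned component with full weight w
    (green -> low anchor, red -> high anchor); no cue reproduces
    :func:`build_prior`. Marginalizing over equiprobable cues recovers the
    no-cue mixture.
    """
    cue = CueCondition.coerce(cue)
    if cue is CueCondition.NONE:
        return build_prior(w, params, grid)
    if not 0.0 <= w <= 1.0:
        raise ParameterError(f"w must lie in [0, 1], got {w}")
    anchor = params.s_low if cue is CueCondition.GREEN else params.s_high
    uniform = np.full(grid.n_points, 1.0 / grid.n_points)
    mass = (1.0 - w) * uniform
    if w > 0:
        mass = mass + w * gaussian_pmf(grid, anchor, params.sigma_prior)
    return BeliefDistribution(grid, mass)


# ---------------------------------------------------------------------------
# inference and decision
# ---------------------------------------------------------------------------

def posterior(
    prior: BeliefDistribution, kernel: LikelihoodKernel, n: float
) -> BeliefDistribution:
    """Posterior over effects given an observed nociceptor signal ``n``."""
    if prior.grid != kernel.grid:
        raise InputError("prior and kernel must share the same grid")
    return BeliefDistribution.from_unnormalized(prior.grid, prior.mass * kernel.likelihood(n))


def map_estimate(post: BeliefDistribution) -> float:
    """MAP decision: the grid intensity of maximal posterior mass.

    Exact ties resolve deterministically to the lowest tied intensity.
    """
    return post.argmax_point()


def map_curve(prior: BeliefDistribution, kernel: LikelihoodKernel) -> np.ndarray:
    """MAP estimate E-hat as a function of every possible signal ``n``.

    Returns an array aligned with the grid; entries are NaN where the
    unnormalized posterior vanishes (possible only without a uniform floor).
    """
    if prior.grid != kernel.grid:
        raise InputError("prior and kernel must share the same grid")
    unnorm = prior.mass[:, None] * kernel.density_columns()  # (e, n)
    col_tot = unnorm.sum(axis=0)
    ehat = prior.grid.points[np.argmax(unnorm, axis=0)].astype(float)
    ehat[col_tot <= 1e-250] = np.nan
    return ehat


def _rating_mixture(
    grid: IntensityGrid, signal_weights: np.ndarray, ehat: np.ndarray, sigma_rating: float
) -> BeliefDistribution:
    """Accumulate Gaussian rating components N(E-hat(n), sigma_rating)."""
    bad = np.isnan(ehat)
    if np.any(bad):
        if signal_weights[bad].sum() > 1e-9:
            raise DegeneratePosteriorError(
                "posterior vanishes for signals carrying non-negligible probability; "
                "w = 1 with an observation far from both conditioned components"
            )
        signal_weights = np.where(bad, 0.0, signal_weights)
        ehat = np.where(bad, grid.points, ehat)
    uniq, inverse = np.unique(ehat, return_inverse=True)
    agg = np.zeros(len(uniq))
    np.add.at(agg, inverse, signal_weights)
    # raw densities, one final normalization: per-component renormalization
    # would systematically inflate components truncated at the grid edges
    components = gaussian_density_matrix(grid, uniq, sigma_rating)
    return BeliefDistribution.from_unnormalized(grid, agg @ components)


def rating_distribution(
    s: float,
    cue: CueCondition | str,
    params: SubjectParams,
    grid: IntensityGrid | None = None,
    kernel: LikelihoodKernel | None = None,
) -> BeliefDistribution:
    """Predicted rating distribution Pr(R | S, C).

    Exact grid marginalization of the generative chain: the signal n follows
    the discretized N(s, sd_nociceptor); each n is decided into E-hat(n, C)
    by posterior maximization; ratings add N(E-hat, sigma_rating) noise.
    """
    if grid is None:
        grid = IntensityGrid()
    if kernel is None:
        kernel = likelihood_kernel(grid, params.sd_nociceptor)
    prior = build_cue_prior(cue, params.w, params, grid)
    ehat = map_curve(prior, kernel)
    weights = gaussian_pmf(grid, s, params.sd_nociceptor)
    return _rating_mixture(grid, weights, ehat, params.sigma_rating)


@dataclass(frozen=True)
class PredictionSurface:
    """Pr(R|S) for every stimulus on the grid, plus the most-probable-rating ridge."""

    grid: IntensityGrid
    cue: CueCondition
    matrix: np.ndarray  # rows: stimuli, columns: ratings; each row sums to 1
    ridge: np.ndarray  # argmax rating per stimulus row

    def row(self, s: float) -> BeliefDistribution:
        return BeliefDistribution(self.grid, self.matrix[self.grid.index_of(s)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.matrix, index=self.grid.points, columns=self.grid.points
        ).rename_axis(index="stimulus", columns="rating")

    def plot(self, ax=None):
        """Heat map of Pr(R|S) with the ridge overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scaled = self.matrix / self.matrix.max(axis=1, keepdims=True)
        ax.imshow(
            scaled.T,
            origin="lower",
            aspect="auto",
            extent=(self.grid.lo, self.grid.hi, self.grid.lo, self.grid.hi),
            cmap="magma",
        )
        ax.plot(self.grid.points, self.ridge, color="orange", lw=1.5)
        ax.set_xlabel("stimulus intensity")
        ax.set_ylabel("pain rating")
        ax.set_title(f"cue = {self.cue.value}")
        return ax


def prediction_surface(
    cue: CueCondition | str,
    params: SubjectParams,
    grid: IntensityGrid | None = None,
) -> PredictionSurface:
    """Rating distribution for every stimulus intensity under one cue."""
    if grid is None:
        grid = IntensityGrid()
    cue = CueCondition.coerce(cue)
    kernel = likelihood_kernel(grid, params.sd_nociceptor)
    prior = build_cue_prior(cue, params.w, params, grid)
    ehat = map_curve(prior, kernel)

    bad = np.isnan(ehat)
    signal_rows = kernel.matrix  # row s: Pr(N|S=s), same Gaussian family
    if np.any(bad):
        if np.any(signal_rows[:, bad].sum(axis=1) > 1e-9):
            raise DegeneratePosteriorError(
                "posterior vanishes over signals reachable from some stimulus"
            )
        ehat = np.where(bad, grid.points, ehat)
        signal_rows = np.where(bad[None, :], 0.0, signal_rows)

    uniq, inverse = np.unique(ehat, return_inverse=True)
    components = gaussian_density_matrix(grid, uniq, params.sigma_rating)
    agg = np.zeros((grid.n_points, len(uniq)))
    np.add.at(agg.T, inverse, signal_rows.T)
    matrix = agg @ components
    matrix /= matrix.sum(axis=1, keepdims=True)
    ridge = grid.points[np.argmax(matrix, axis=1)].astype(float)
    return PredictionSurface(grid, cue, matrix, ridge)


def posterior_for_trial(
    n: float,
    cue: CueCondition | str,
    params: SubjectParams,
    grid: IntensityGrid | None = None,
) -> BeliefDistribution:
    """Convenience: cue-conditioned posterior for a single observed signal."""
    if grid is None:
        grid = IntensityGrid()
    kernel = likelihood_kernel(grid, params.sd_nociceptor)
    prior = build_cue_prior(cue, params.w, params, grid)
    return posterior(prior, kernel, n)
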