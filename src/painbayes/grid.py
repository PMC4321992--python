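"""Discretized intensity axis and probability containers.

Everything the observer reasons about — the stimulus effect E, the nociceptor
signal N, the delivered stimulus S and the reported rating R — lives on one
common axis of arbitrary intensity units, by default 0–100 in steps of 0.5.
Probability distributions over that axis are represented as normalized mass
vectors (:class:`BeliefDistribution`); the Gaussian sensory likelihood is a
row-stochastic matrix (:class:`LikelihoodKernel`).

Discretization convention: continuous densities are evaluated at the grid
points and renormalized to sum to one, so truncation at the grid edges is
absorbed by renormalization rather than reflection.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Sequence

import numpy as np

from .exceptions import InputError, ParameterError

#: tolerance within which every stored probability vector must sum to 1
NORMALIZATION_TOL = 1e-9

#: unnormalized mass below this total is treated as numerically degenerate
_DEGENERATE_FLOOR = 1e-250


@dataclass(frozen=True)
class IntensityGrid:
    """Regular grid of intensities shared by all distributions.

    Parameters
    ----------
    lo, hi : float
        Inclusive range of the axis (default 0–100 arbitrary units).
    step : float
        Grid spacing; must divide ``hi - lo`` exactly.
    """

    lo: float = 0.0
    hi: float = 100.0
    step: float = 0.5

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ParameterError(f"grid requires lo < hi, got [{self.lo}, {self.hi}]")
        if self.step <= 0:
            raise ParameterError(f"grid step must be positive, got {self.step}")
        ratio = (self.hi - self.lo) / self.step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ParameterError(
                f"grid step {self.step} does not divide the range [{self.lo}, {self.hi}] exactly"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.hi - self.lo) / self.step)) + 1

    @cached_property
    def points(self) -> np.ndarray:
        pts = self.lo + self.step * np.arange(self.n_points)
        pts.setflags(write=False)
        return pts

    def index_of(self, x: float) -> int:
        """Index of the grid point nearest ``x``.

        ``x`` may lie up to half a step outside the range; anything further is
        rejected rather than silently clamped.
        """
        if x < self.lo - self.step / 2 - 1e-12 or x > self.hi + self.step / 2 + 1e-12:
            raise InputError(f"value {x} lies outside grid range [{self.lo}, {self.hi}]")
        return int(np.clip(round((x - self.lo) / self.step), 0, self.n_points - 1))

    def indices_of(self, xs: Sequence[float]) -> np.ndarray:
        xs = np.asarray(xs, dtype=float)
        if np.any(xs < self.lo - self.step / 2 - 1e-12) or np.any(
            xs > self.hi + self.step / 2 + 1e-12
        ):
            raise InputError("values lie outside the grid range")
        return np.clip(np.round((xs - self.lo) / self.step), 0, self.n_points - 1).astype(int)


def gaussian_pmf(grid: IntensityGrid, mean: float, sd: float) -> np.ndarray:
    """Discretized Gaussian: density at the grid points, renormalized.

    This is the single discretization primitive of the package; priors,
    likelihood rows and rating components are all built from it.
    """
    if sd <= 0:
        raise ParameterError(f"standard deviation must be positive, got {sd}")
    z = (grid.points - mean) / sd
    dens = np.exp(-0.5 * z * z)
    total = dens.sum()
    if total <= _DEGENERATE_FLOOR:
        # mean so far outside the grid that every point underflows
        raise ParameterError(
            f"Gaussian(mean={mean}, sd={sd}) has no numerical support on the grid"
        )
    return dens / total


def gaussian_pmf_matrix(grid: IntensityGrid, means: np.ndarray, sd: float) -> np.ndarray:
    """Rows of discretized Gaussians, one per entry of ``means``."""
    if sd <= 0:
        raise ParameterError(f"standard deviation must be positive, got {sd}")
    z = (grid.points[None, :] - np.asarray(means, dtype=float)[:, None]) / sd
    dens = np.exp(-0.5 * z * z)
    totals = dens.sum(axis=1, keepdims=True)
    if np.any(totals <= _DEGENERATE_FLOOR):
        raise ParameterError("a Gaussian row has no numerical support on the grid")
    return dens / totals


def gaussian_density_matrix(grid: IntensityGrid, means: np.ndarray, sd: float) -> np.ndarray:
    """Rows of *unnormalized* Gaussian densities at the grid points.

    Used where several Gaussian components are mixed and the mixture is
    normalized once at the end: renormalizing each component individually
    would inflate components whose mass is truncated at the grid edges.
    """
    if sd <= 0:
        raise ParameterError(f"standard deviation must be positive, got {sd}")
    z = (grid.points[None, :] - np.asarray(means, dtype=float)[:, None]) / sd
    return np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class BeliefDistribution:
    """Normalized probability mass over an :class:`IntensityGrid`.

    The normalization constant of Bayes' rule is absorbed here: any
    construction path must hand in mass summing to one (use
    :meth:`from_unnormalized` otherwise).
    """

    grid: IntensityGrid
    mass: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        if mass.shape != (self.grid.n_points,):
            raise InputError(
                f"mass has shape {mass.shape}, expected ({self.grid.n_points},)"
            )
        if np.any(~np.isfinite(mass)) or np.any(mass < 0):
            raise InputError("mass must be finite and non-negative")
        if abs(mass.sum() - 1.0) > NORMALIZATION_TOL:
            raise InputError(f"mass sums to {mass.sum():.12f}, expected 1 within 1e-9")
        mass.setflags(write=False)
        object.__setattr__(self, "mass", mass)

    @classmethod
    def from_unnormalized(cls, grid: IntensityGrid, weights: np.ndarray) -> "BeliefDistribution":
        weights = np.asarray(weights, dtype=float)
        total = weights.sum()
        if not np.isfinite(total) or total <= _DEGENERATE_FLOOR:
            from .exceptions import DegeneratePosteriorError

            raise DegeneratePosteriorError(
                "unnormalized mass is (numerically) zero everywhere"
            )
        return cls(grid, weights / total)

    # -- summaries ---------------------------------------------------------
    def mean(self) -> float:
        return float(self.mass @ self.grid.points)

    def variance(self) -> float:
        mu = self.mean()
        return float(self.mass @ (self.grid.points - mu) ** 2)

    def argmax_point(self) -> float:
        """Grid point of maximal mass; exact ties resolve to the lowest intensity."""
        return float(self.grid.points[int(np.argmax(self.mass))])

    def local_maxima(
        self, rel_tol: float = 1e-12, min_rel_height: float = 1e-3
    ) -> np.ndarray:
        """Grid points that are local maxima of the mass profile.

        Flat stretches (plateaus) count once, at their lowest intensity.
        Maxima whose mass is below ``min_rel_height`` times the global
        maximum are ignored: they are numerical dust (e.g. where the uniform
        prior floor re-emerges many s.d. away from every mixture component)
        rather than modes of the distribution.
        """
        m = self.mass
        scale = m.max() * rel_tol
        # collapse numerically-flat runs before comparing neighbours
        keep = np.ones(len(m), dtype=bool)
        keep[1:] = np.abs(np.diff(m)) > scale
        idx = np.flatnonzero(keep)
        vals = m[idx]
        floor = m.max() * min_rel_height
        maxima = []
        for k in range(len(idx)):
            left = vals[k - 1] if k > 0 else -np.inf
            right = vals[k + 1] if k < len(idx) - 1 else -np.inf
            if vals[k] > left and vals[k] > right and vals[k] >= floor:
                maxima.append(self.grid.points[idx[k]])
        return np.asarray(maxima)

    def log_mass_at(self, xs: Sequence[float]) -> np.ndarray:
        """Natural log of the mass at the grid points nearest ``xs``.

        Zero mass maps to ``-inf`` (callers decide how to treat it).
        """
        idx = self.grid.indices_of(xs)
        with np.errstate(divide="ignore"):
            return np.log(self.mass[idx])


@dataclass(frozen=True)
class LikelihoodKernel:
    """Gaussian sensory kernel ``Pr(N | E)``.

    ``matrix`` is the row-stochastic restriction to the grid,
    ``P[j, i] = Pr(N = n_i | E = e_j)``, each row a discretized Gaussian
    centred on ``means[j] = mu(e_j)`` with common standard deviation ``sd``,
    renormalized over the grid. The *likelihood function* used in Bayes'
    rule, :meth:`likelihood`, evaluates the untruncated Gaussian density of
    an observed signal ``n``: the signal axis is conceptually unbounded, so
    conditioning on ``n`` must not inherit the grid-edge truncation of the
    rows (row renormalization inflates edge rows and would bias the
    posterior toward the boundary for near-edge signals).
    """

    grid: IntensityGrid
    matrix: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)
    sd: float = 0.0

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        means = np.asarray(self.means, dtype=float)
        n = self.grid.n_points
        if mat.shape != (n, n):
            raise InputError(f"kernel matrix has shape {mat.shape}, expected ({n}, {n})")
        if means.shape != (n,):
            raise InputError(f"kernel means have shape {means.shape}, expected ({n},)")
        if np.any(~np.isfinite(mat)) or np.any(mat < 0):
            raise InputError("kernel entries must be finite and non-negative")
        if np.any(np.abs(mat.sum(axis=1) - 1.0) > NORMALIZATION_TOL):
            raise InputError("every kernel row must sum to 1 within 1e-9")
        mat.setflags(write=False)
        means.setflags(write=False)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "means", means)

    def row(self, e: float) -> np.ndarray:
        """Distribution of the signal N over the grid for a fixed effect ``e``."""
        return self.matrix[self.grid.index_of(e)]

    def likelihood(self, n: float) -> np.ndarray:
        """Likelihood of each effect ``e`` for an observed signal ``n``.

        ``n`` may be any real value, on or off the grid.
        """
        z = (float(n) - self.means) / self.sd
        return np.exp(-0.5 * z * z)

    def density_columns(self) -> np.ndarray:
        """Likelihood values for every grid signal: ``L[j, i] = phi(n_i; mu(e_j), sd)``."""
        z = (self.grid.points[None, :] - self.means[:, None]) / self.sd
        return np.exp(-0.5 * z * z)


def likelihood_kernel(
    grid: IntensityGrid,
    sd: float,
    mu_map: Callable[[np.ndarray], np.ndarray] | None = None,
) -> LikelihoodKernel:
    """Gaussian sensory kernel ``Pr(N | E)`` on the grid.

    ``mu_map`` maps effects to expected signals; the default is the identity,
    i.e. the nociceptor signal is calibrated to the intensity axis.
    """
    means = grid.points if mu_map is None else np.asarray(mu_map(grid.points), dtype=float)
    return LikelihoodKernel(grid, gaussian_pmf_matrix(grid, means, sd), means, sd)
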