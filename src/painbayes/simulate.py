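"""Synthetic cohorts run through the two experimental designs.

Subjects are simulated trial by trial from the generative chain of the full
Bayesian decision observer: the nociceptor signal n is drawn around the
delivered intensity, decided into a perceived intensity by cue-conditioned
posterior maximization, and reported with Gaussian rating noise truncated at
the VAS floor of zero. Conditioning is modelled as instantaneous: during the
training blocks the subject has no conditioned expectation yet and rates
with a flat prior; from the first test block onward the full mixture prior
(weight w) is in place. Cohorts can also be generated from the no-learn
competitor model for identifiability and power studies.

Determinism: a master seed expands into per-subject seeds through
``numpy.random.SeedSequence(master_seed).spawn``, so cohorts are exactly
reproducible and subjects are independent streams.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .alt_models import ConditioningStats, no_learn_predictive
from .design import ExperimentDesign, make_design
from .exceptions import InputError, ParameterError
from .grid import IntensityGrid, likelihood_kernel
from .observer import CueCondition, SubjectParams, build_cue_prior, map_curve

__all__ = ["CohortSpec", "simulate_subject", "simulate_cohort", "RATING_COLUMNS"]

RATING_COLUMNS = [
    "subject_id",
    "experiment",
    "block",
    "trial",
    "cue",
    "stimulus_level",
    "stimulus_intensity",
    "vas_raw",
    "vas_scaled",
]


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Draws from N(mean, sd) truncated to >= 0 (VAS floor), via resampling."""
    mean = np.asarray(mean, dtype=float)
    out = rng.normal(mean, sd)
    for _ in range(1000):
        bad = out < 0
        if not np.any(bad):
            return out
        out[bad] = rng.normal(mean[bad], sd)
    raise ParameterError("rating truncation failed to converge; mean far below zero")


def simulate_subject(
    params: SubjectParams,
    design: ExperimentDesign,
    seed,
    subject_id: int = 0,
    grid: IntensityGrid | None = None,
    generator: Literal["fbd", "no_learn"] = "fbd",
) -> pd.DataFrame:
    """Trial-level VAS rating records for one subject.

    ``generator="fbd"`` runs the full Bayesian decision chain;
    ``"no_learn"`` keeps the same (expectation-free) conditioning blocks but
    draws test-block ratings from the no-learn predictive built from the
    subject's own conditioning ratings.
    """
    if grid is None:
        grid = IntensityGrid()
    if generator not in ("fbd", "no_learn"):
        raise InputError(f"unknown generator {generator!r}")
    rng = np.random.default_rng(seed)
    kernel = likelihood_kernel(grid, params.sd_nociceptor)

    # decision curves E-hat(n) for the flat-prior (conditioning) state and
    # for each cue in the conditioned state
    naive = map_curve(build_cue_prior(CueCondition.NONE, 0.0, params, grid), kernel)
    conditioned = {
        cue: map_curve(build_cue_prior(cue, params.w, params, grid), kernel)
        for cue in CueCondition
    }

    rows: list[dict] = []
    cond_ratings: dict[str, list[float]] = {"low": [], "high": []}
    for block_idx, block in enumerate(design.blocks):
        is_conditioning = block_idx in design.conditioning_blocks
        for trial_idx, trial in enumerate(block):
            s = params.anchor(trial.level)
            if generator == "no_learn" and not is_conditioning:
                stats = ConditioningStats.from_ratings(
                    cond_ratings["low"], cond_ratings["high"]
                )
                pred_mean = no_learn_predictive(
                    stats, s, grid, s_low=params.s_low, s_high=params.s_high
                ).mean()
                # no-learn: unimodal Gaussian around the interpolated mean
                vas = float(_truncated_normal(rng, np.array([pred_mean]), stats.pooled_sd)[0])
            else:
                n = rng.normal(s, params.sd_nociceptor)
                n_idx = int(np.clip(round((n - grid.lo) / grid.step), 0, grid.n_points - 1))
                curve = naive if is_conditioning else conditioned[trial.cue]
                ehat = curve[n_idx]
                if np.isnan(ehat):
                    from .exceptions import DegeneratePosteriorError

                    raise DegeneratePosteriorError(
                        f"posterior vanished for signal {n:.2f} (subject {subject_id})"
                    )
                vas = float(_truncated_normal(rng, np.array([ehat]), params.sigma_rating)[0])
            if is_conditioning:
                cond_ratings[trial.level].append(vas)
            rows.append(
                {
                    "subject_id": subject_id,
                    "experiment": design.experiment,
                    "block": block_idx,
                    "trial": trial_idx,
                    "cue": trial.cue.value,
                    "stimulus_level": trial.level,
                    "stimulus_intensity": s,
                    "vas_raw": vas,
                    "vas_scaled": np.nan,
                }
            )
    return pd.DataFrame(rows, columns=RATING_COLUMNS)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``w`` may be a single float (homogeneous cohort), a ``(lo, hi)`` tuple
    (per-subject w drawn uniformly), or an explicit per-subject sequence.
    ``base_params`` carries every other subject parameter; its own ``w`` is
    ignored.
    """

    n_subjects: int
    experiment: int = 2
    w: float | tuple[float, float] | Sequence[float] = (0.0, 1.0)
    base_params: SubjectParams = field(default_factory=lambda: SubjectParams(w=0.5))
    master_seed: int = 0
    generator: Literal["fbd", "no_learn"] = "fbd"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("cohort needs at least one subject")
        if self.experiment not in (1, 2):
            raise InputError(f"unknown experiment id {self.experiment}")

    def draw_w(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.w, (int, float)):
            ws = np.full(self.n_subjects, float(self.w))
        elif isinstance(self.w, tuple) and len(self.w) == 2:
            ws = rng.uniform(self.w[0], self.w[1], size=self.n_subjects)
        else:
            ws = np.asarray(self.w, dtype=float)
            if ws.shape != (self.n_subjects,):
                raise ParameterError(
                    f"explicit w sequence has length {ws.size}, expected {self.n_subjects}"
                )
        if np.any((ws < 0) | (ws > 1)):
            raise ParameterError("w values must lie in [0, 1]")
        return ws


def simulate_cohort(
    spec: CohortSpec, grid: IntensityGrid | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns ``(records, truth)``: the concatenated trial-level rating table
    and the ground-truth per-subject parameter table used for recovery
    studies.
    """
    if grid is None:
        grid = IntensityGrid()
    root = np.random.SeedSequence(spec.master_seed)
    cohort_ss, *subject_ss = root.spawn(spec.n_subjects + 1)
    ws = spec.draw_w(np.random.default_rng(cohort_ss))

    frames = []
    truth_rows = []
    for sid, (w, ss) in enumerate(zip(ws, subject_ss)):
        params = spec.base_params.with_w(float(w))
        design = make_design(spec.experiment, np.random.default_rng(ss.spawn(1)[0]))
        frames.append(
            simulate_subject(
                params, design, ss, subject_id=sid, grid=grid, generator=spec.generator
            )
        )
        truth_rows.append(
            {
                "subject_id": sid,
                "w": float(w),
                "sigma_prior": params.sigma_prior,
                "sd_nociceptor": params.sd_nociceptor,
                "sigma_rating": params.sigma_rating,
                "s_low": params.s_low,
                "s_mid": params.s_mid,
                "s_high": params.s_high,
                "generator": spec.generator,
            }
        )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth_rows)
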