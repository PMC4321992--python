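"""Data preparation and per-subject parameter estimation.

VAS scaling follows the study convention: within each subject and block,
scores are expressed relative to the mean response to the high stimuli of
that block (the placebo block uses the red-cued high stimuli as reference),
so the reference mean maps to 100.

Parameter fitting is likelihood-based on a deterministic grid: the model
defines a full predicted rating distribution for every (stimulus, cue), so
the expectation weight w (and optionally the prior dispersion sigma) is
estimated by maximizing the log-likelihood of the subject's placebo-block
ratings over a regular parameter grid. Grid search keeps the estimate exactly
reproducible; ties resolve to the smallest parameter value.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError, ScalingError, UndefinedCorrelationError
from .grid import BeliefDistribution, IntensityGrid, likelihood_kernel
from .observer import CueCondition, SubjectParams, build_cue_prior, map_curve

__all__ = [
    "FitResult",
    "scale_vas",
    "predictive_bank",
    "fit_w",
    "fit_sigma",
    "placebo_magnitude",
    "explained_variance",
]


# ---------------------------------------------------------------------------
# VAS scaling
# ---------------------------------------------------------------------------

def scale_vas(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``vas_scaled``: 100 x rating / reference mean, per subject per block.

    The reference within a block is the mean of the high-stimulus ratings;
    in a placebo block (one containing green-cued high stimuli) only the
    red-cued high stimuli define the reference.
    """
    required = {"subject_id", "block", "cue", "stimulus_level", "vas_raw"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"rating table lacks columns {sorted(missing)}")
    out = records.copy()
    out["vas_scaled"] = np.nan
    for (subject, block), group in out.groupby(["subject_id", "block"], sort=False):
        high = group[group["stimulus_level"] == "high"]
        is_placebo = bool((high["cue"] == "green").any())
        ref = high[high["cue"] == "red"] if is_placebo else high
        if ref.empty:
            raise ScalingError(
                f"no reference high-stimulus ratings for subject {subject}, block {block}"
            )
        ref_mean = float(ref["vas_raw"].mean())
        if ref_mean <= 0:
            raise ScalingError(
                f"non-positive reference mean ({ref_mean}) for subject {subject}, block {block}"
            )
        out.loc[group.index, "vas_scaled"] = 100.0 * group["vas_raw"] / ref_mean
    return out


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def predictive_bank(
    params: SubjectParams,
    grid: IntensityGrid,
    stimuli: Iterable[float],
    cues: Iterable[CueCondition | str],
    w_values: np.ndarray,
) -> dict[tuple[float, str, float], BeliefDistribution]:
    """Predicted rating distributions for every (w, cue, stimulus) combination.

    The MAP decision curve depends on (w, cue) but not on the stimulus, so it
    is computed once per (w, cue) and reused across stimuli.
    """
    from .observer import _rating_mixture
    from .grid import gaussian_pmf

    kernel = likelihood_kernel(grid, params.sd_nociceptor)
    stimuli = list(dict.fromkeys(float(s) for s in stimuli))
    cues = [CueCondition.coerce(c) for c in cues]
    weights = {s: gaussian_pmf(grid, s, params.sd_nociceptor) for s in stimuli}
    bank: dict[tuple[float, str, float], BeliefDistribution] = {}
    for w in w_values:
        for cue in cues:
            prior = build_cue_prior(cue, float(w), params, grid)
            ehat = map_curve(prior, kernel)
            for s in stimuli:
                bank[(float(w), cue.value, s)] = _rating_mixture(
                    grid, weights[s], ehat, params.sigma_rating
                )
    return bank


@dataclass(frozen=True)
class FitResult:
    """Outcome of a per-subject grid fit."""

    subject_id: int | str
    w_hat: float
    loglik: float
    sigma_hat: float | None = None
    sigma_rating_hat: float | None = None
    n_trials: int = 0
    diagnostics: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "w_hat": self.w_hat,
            "sigma_hat": self.sigma_hat,
            "sigma_rating_hat": self.sigma_rating_hat,
            "loglik": self.loglik,
            "n_trials": self.n_trials,
        }


def _placebo_trials(records: pd.DataFrame, rating_col: str) -> pd.DataFrame:
    """High-stimulus cued trials of the placebo test block."""
    mask = (records["stimulus_level"] == "high") & records["cue"].isin(["green", "red"])
    if "block" in records.columns:
        # restrict to the latest block containing green-cued high stimuli
        cand = records[mask]
        if cand.empty:
            raise InputError("no cued high-stimulus trials found")
        placebo_blocks = cand.loc[cand["cue"] == "green", "block"]
        if placebo_blocks.empty:
            raise InputError("no green-cued high-stimulus trials found")
        block = placebo_blocks.max()
        cand = cand[cand["block"] == block]
    else:
        cand = records[mask]
    cand = cand.dropna(subset=[rating_col])
    if cand.empty:
        raise InputError("placebo block has no usable ratings")
    return cand


def _loglik_for_ratings(
    pred: BeliefDistribution, ratings: np.ndarray
) -> float:
    grid = pred.grid
    clamped = np.clip(ratings, grid.lo, grid.hi)
    return float(pred.log_mass_at(clamped).sum())


def fit_w(
    records: pd.DataFrame,
    params: SubjectParams,
    grid: IntensityGrid | None = None,
    *,
    w_step: float = 0.01,
    rating_col: str = "vas_raw",
    bank: Mapping[tuple[float, str, float], BeliefDistribution] | None = None,
    subject_id: int | str | None = None,
    s_stimulus: float | None = None,
) -> FitResult:
    """Estimate the expectation weight w of one subject.

    Maximizes, over a regular w grid, the joint log-likelihood of the
    subject's placebo-block ratings (both green- and red-cued high stimuli)
    under the predicted rating distribution; exact ties resolve to the
    smaller w. All other parameters are taken from ``params``.
    """
    if grid is None:
        grid = IntensityGrid()
    trials = _placebo_trials(records, rating_col)
    greens = trials.loc[trials["cue"] == "green", rating_col].to_numpy(dtype=float)
    reds = trials.loc[trials["cue"] == "red", rating_col].to_numpy(dtype=float)
    if greens.size == 0 or reds.size == 0:
        raise InputError("fit_w needs at least one green- and one red-cued high rating")
    if s_stimulus is not None:
        s_high = float(s_stimulus)
    elif "stimulus_intensity" in trials and rating_col == "vas_raw":
        s_high = float(trials["stimulus_intensity"].iloc[0])
    else:
        s_high = params.s_high

    w_values = np.round(np.arange(0.0, 1.0 + w_step / 2, w_step), 10)
    if bank is None:
        bank = predictive_bank(params, grid, [s_high], ["green", "red"], w_values)
    logliks = np.empty(w_values.size)
    for i, w in enumerate(w_values):
        ll = _loglik_for_ratings(bank[(float(w), "green", s_high)], greens)
        ll += _loglik_for_ratings(bank[(float(w), "red", s_high)], reds)
        logliks[i] = ll
    best = int(np.argmax(logliks))  # first (= smallest w) among exact ties
    if subject_id is None:
        subject_id = trials["subject_id"].iloc[0] if "subject_id" in trials else 0
    return FitResult(
        subject_id=subject_id,
        w_hat=float(w_values[best]),
        loglik=float(logliks[best]),
        sigma_hat=None,
        sigma_rating_hat=params.sigma_rating,
        n_trials=int(greens.size + reds.size),
        diagnostics={"w_grid_step": w_step, "loglik_range": float(np.ptp(logliks))},
    )


def fit_sigma(
    records: pd.DataFrame,
    grid: IntensityGrid | None = None,
    *,
    params: SubjectParams | None = None,
    sigma_values: np.ndarray | None = None,
    w_step: float = 0.05,
    rating_col: str = "vas_raw",
) -> tuple[pd.DataFrame, dict]:
    """Joint per-subject grid fit of (sigma, w) on conditioning + placebo data.

    For each subject the conditioning-block rating means fix the locations of
    the two prior components; the placebo-block likelihood is then maximized
    over a (sigma, w) grid. Returns the per-subject table and the cohort
    summary (mean and s.d. of the sigma estimates).
    """
    if grid is None:
        grid = IntensityGrid()
    if params is None:
        params = SubjectParams(w=0.5)
    if sigma_values is None:
        sigma_values = np.arange(2.0, 12.01, 0.5)
    w_values = np.round(np.arange(0.0, 1.0 + w_step / 2, w_step), 10)

    rows = []
    for subject, sub in records.groupby("subject_id", sort=True):
        cond = sub[sub["block"].isin([0, 1])]
        low = cond.loc[cond["stimulus_level"] == "low", rating_col].to_numpy(dtype=float)
        high = cond.loc[cond["stimulus_level"] == "high", rating_col].to_numpy(dtype=float)
        if low.size < 2 or high.size < 2:
            raise InputError(f"subject {subject}: insufficient conditioning trials")
        trials = _placebo_trials(sub, rating_col)
        greens = trials.loc[trials["cue"] == "green", rating_col].to_numpy(dtype=float)
        reds = trials.loc[trials["cue"] == "red", rating_col].to_numpy(dtype=float)
        if greens.size == 0 or reds.size == 0:
            raise InputError(f"subject {subject}: placebo block incomplete")
        if float(np.ptp(np.concatenate([greens, reds]))) == 0.0:
            rows.append(
                {
                    "subject_id": subject,
                    "sigma_hat": np.nan,
                    "w_hat": np.nan,
                    "loglik": np.nan,
                    "degenerate": True,
                }
            )
            continue
        mean_low, mean_high = float(low.mean()), float(high.mean())
        if mean_low >= mean_high:
            rows.append(
                {
                    "subject_id": subject,
                    "sigma_hat": np.nan,
                    "w_hat": np.nan,
                    "loglik": np.nan,
                    "degenerate": True,
                }
            )
            continue
        s_high = float(trials["stimulus_intensity"].iloc[0])
        best = (-np.inf, np.nan, np.nan)
        for sigma in sigma_values:
            p = SubjectParams(
                w=0.5,
                sigma_prior=float(sigma),
                sd_nociceptor=params.sd_nociceptor,
                sigma_rating=params.sigma_rating,
                s_low=mean_low,
                s_mid=(mean_low + mean_high) / 2,
                s_high=mean_high,
            )
            bank = predictive_bank(p, grid, [s_high], ["green", "red"], w_values)
            for w in w_values:
                ll = _loglik_for_ratings(bank[(float(w), "green", s_high)], greens)
                ll += _loglik_for_ratings(bank[(float(w), "red", s_high)], reds)
                if ll > best[0]:
                    best = (ll, float(sigma), float(w))
        rows.append(
            {
                "subject_id": subject,
                "sigma_hat": best[1],
                "w_hat": best[2],
                "loglik": best[0],
                "degenerate": False,
            }
        )
    table = pd.DataFrame(rows)
    valid = table.loc[~table["degenerate"], "sigma_hat"]
    summary = {
        "sigma_mean": float(valid.mean()) if len(valid) else np.nan,
        "sigma_sd": float(valid.std(ddof=1)) if len(valid) > 1 else np.nan,
        "n_subjects": int(len(table)),
        "n_degenerate": int(table["degenerate"].sum()),
    }
    return table, summary


# ---------------------------------------------------------------------------
# placebo magnitude and explained variance
# ---------------------------------------------------------------------------

def placebo_magnitude(records: pd.DataFrame, rating_col: str = "vas_scaled") -> float:
    """Percent analgesia: 100 x (mean red-high - mean green-high) / mean red-high.

    Positive values mean the green (sham-treatment) cue lowered the reported
    pain relative to the overt no-treatment (red) cue; negative values are
    nocebo-direction responses.
    """
    trials = _placebo_trials(records, rating_col)
    greens = trials.loc[trials["cue"] == "green", rating_col].to_numpy(dtype=float)
    reds = trials.loc[trials["cue"] == "red", rating_col].to_numpy(dtype=float)
    if greens.size == 0 or reds.size == 0:
        raise InputError("placebo magnitude needs both cue groups")
    red_mean = float(reds.mean())
    if red_mean == 0:
        raise InputError("mean red-cued rating is zero; placebo magnitude undefined")
    return 100.0 * (red_mean - float(greens.mean())) / red_mean


def explained_variance(w_hat, placebo) -> dict:
    """Correlation of fitted expectation with placebo size, and residual variance.

    Returns Pearson r, the one-tailed P for a positive association, and the
    residual variance defined as 100 x (1 - r^2).
    """
    x = np.asarray(w_hat, dtype=float)
    y = np.asarray(placebo, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need equal-length vectors with at least 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    from .stats import pearson_one_tailed

    res = pearson_one_tailed(x, y)
    return {
        "r": res["r"],
        "P_one_tailed": res["P"],
        "residual_variance_percent": 100.0 * (1.0 - res["r"] ** 2),
    }
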