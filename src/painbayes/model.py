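"""Statsmodels-style front end: a model bound to rating data, a results object.

:class:`PlaceboExperiment` wraps a trial-level rating table (one cohort, one
experimental design) together with the observer hyperparameters. ``fit()``
estimates each subject's expectation weight w — and optionally the prior
dispersion sigma — by grid likelihood maximization on the placebo block, and
returns :class:`PlaceboExperimentResults`, which carries the per-subject
estimates and exposes the downstream analyses: the cohort placebo test,
expectation-vs-placebo correlation, per-subject model comparison on the
held-out uncued block, clustering/bimodality of mid-stimulus ratings, and
the correlation table linking expectation to clustering.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .alt_models import ConditioningStats, no_learn_predictive, simple_bayes_predictive
from .exceptions import InputError
from .fitting import (
    explained_variance,
    fit_sigma,
    fit_w,
    placebo_magnitude,
    predictive_bank,
    scale_vas,
)
from .grid import IntensityGrid
from .observer import CueCondition, SubjectParams, rating_distribution
from .stats import (
    bimodality_test,
    model_posteriors,
    pearson_one_tailed,
    signed_rank_one_tailed,
)

__all__ = ["PlaceboExperiment", "PlaceboExperimentResults"]

MODEL_NAMES = ("no_learn", "simple_bayes", "fbd")


class PlaceboExperiment:
    """Bayesian observer model bound to a cohort's rating records.

    Parameters
    ----------
    data : DataFrame
        Trial-level rating records with the columns produced by
        :func:`painbayes.simulate.simulate_cohort` (``vas_scaled`` may be
        unfilled; it is computed on demand).
    params : SubjectParams, optional
        Hyperparameters shared across subjects (the per-subject w in it is
        ignored during fitting). Defaults to the package defaults.
    grid : IntensityGrid, optional
    """

    def __init__(
        self,
        data: pd.DataFrame,
        params: SubjectParams | None = None,
        grid: IntensityGrid | None = None,
    ) -> None:
        required = {"subject_id", "block", "trial", "cue", "stimulus_level", "vas_raw"}
        missing = required - set(data.columns)
        if missing:
            raise InputError(f"rating table lacks columns {sorted(missing)}")
        if data.empty:
            raise InputError("rating table is empty")
        self.data = data.reset_index(drop=True)
        self.params = params if params is not None else SubjectParams(w=0.5)
        self.grid = grid if grid is not None else IntensityGrid()

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PlaceboExperiment":
        return cls(pd.read_csv(path), **kwargs)

    # ------------------------------------------------------------------
    def predict(self, s: float, cue: CueCondition | str, w: float):
        """Predicted rating distribution at the model's hyperparameters."""
        return rating_distribution(s, cue, self.params.with_w(w), self.grid)

    def fit(
        self, *, w_step: float = 0.01, estimate_sigma: bool = False
    ) -> "PlaceboExperimentResults":
        """Per-subject grid likelihood fits on the placebo block.

        With ``estimate_sigma=True`` the prior dispersion is fitted jointly
        with w for each subject (conditioning-block means fixing the prior
        component locations), as done for the first experiment; otherwise
        sigma is held at ``params.sigma_prior``.
        """
        scaled = scale_vas(self.data)
        if estimate_sigma:
            table, summary = fit_sigma(self.data, self.grid, params=self.params)
            fits = table.rename(columns={})
        else:
            w_values = np.round(np.arange(0.0, 1.0 + w_step / 2, w_step), 10)
            bank = predictive_bank(
                self.params, self.grid, [self.params.s_high], ["green", "red"], w_values
            )
            rows = []
            for subject, sub in self.data.groupby("subject_id", sort=True):
                res = fit_w(
                    sub, self.params, self.grid, w_step=w_step, bank=bank, subject_id=subject
                )
                rows.append(
                    {
                        "subject_id": subject,
                        "w_hat": res.w_hat,
                        "sigma_hat": np.nan,
                        "loglik": res.loglik,
                        "degenerate": False,
                    }
                )
            fits = pd.DataFrame(rows)
            summary = {"sigma_mean": np.nan, "sigma_sd": np.nan}
        mags = {
            subject: placebo_magnitude(sub)
            for subject, sub in scaled.groupby("subject_id", sort=True)
        }
        fits["placebo_magnitude"] = fits["subject_id"].map(mags)
        return PlaceboExperimentResults(
            model=self, fits=fits, scaled=scaled, sigma_summary=summary
        )


def _conditioning_stats_scaled(sub: pd.DataFrame) -> ConditioningStats:
    cond = sub[sub["block"].isin([0, 1])]
    low = cond.loc[cond["stimulus_level"] == "low", "vas_scaled"].to_numpy(dtype=float)
    high = cond.loc[cond["stimulus_level"] == "high", "vas_scaled"].to_numpy(dtype=float)
    return ConditioningStats.from_ratings(low, high)


def compare_models_subject(
    sub: pd.DataFrame,
    params: SubjectParams,
    *,
    w_step: float = 0.02,
    comparison_grid: IntensityGrid | None = None,
) -> dict:
    """Three-way model comparison for one subject of the four-block design.

    Works on intra-block scaled VAS scores throughout. The conditioning
    blocks calibrate each model: their rating means fix the component
    locations and their standard deviations the rating variability; the
    nociceptor and prior widths are rescaled from intensity units by the
    ratio of the conditioned separation on the two scales. The expectation
    weight w is fitted on the placebo (fourth) block, and the three
    predictive distributions are evaluated on the held-out mid-intensity
    ratings of the uncued third block, under equal model priors.
    """
    if comparison_grid is None:
        # scaled scores reach above 100 (the reference mean maps to 100)
        comparison_grid = IntensityGrid(0.0, 160.0, 0.5)
    if "vas_scaled" not in sub or sub["vas_scaled"].isna().all():
        sub = scale_vas(sub)
    stats = _conditioning_stats_scaled(sub)
    mid = sub[(sub["block"] == 2) & (sub["stimulus_level"] == "mid")]
    mid_ratings = mid["vas_scaled"].to_numpy(dtype=float)
    if mid_ratings.size == 0:
        raise InputError("subject has no mid-intensity uncued ratings")
    if stats.mean_low >= stats.mean_high:
        return {"scores": None, "degenerate": True, "w_hat": np.nan, "stats": stats}

    # calibrate widths to the scaled axis via the conditioned separation
    scale = (stats.mean_high - stats.mean_low) / (params.s_high - params.s_low)
    sigma_rating = max(stats.pooled_sd, 0.5)
    fbd_params = SubjectParams(
        w=0.5,
        sigma_prior=params.sigma_prior * scale,
        sd_nociceptor=params.sd_nociceptor * scale,
        sigma_rating=sigma_rating,
        s_low=stats.mean_low,
        s_mid=(stats.mean_low + stats.mean_high) / 2,
        s_high=stats.mean_high,
    )
    fit = fit_w(
        sub,
        fbd_params,
        comparison_grid,
        w_step=w_step,
        rating_col="vas_scaled",
    )
    s_mid_scaled = fbd_params.s_mid
    predictives = {
        "no_learn": no_learn_predictive(
            stats, s_mid_scaled, comparison_grid,
            s_low=stats.mean_low, s_high=stats.mean_high,
        ),
        "simple_bayes": simple_bayes_predictive(
            stats, s_mid_scaled, "none", fbd_params, comparison_grid
        ),
        "fbd": rating_distribution(
            s_mid_scaled, "none", fbd_params.with_w(fit.w_hat), comparison_grid
        ),
    }
    scores = model_posteriors(mid_ratings, predictives)
    return {"scores": scores, "degenerate": False, "w_hat": fit.w_hat, "stats": stats}


@dataclass
class PlaceboExperimentResults:
    """Estimates and derived analyses for a fitted cohort."""

    model: PlaceboExperiment
    fits: pd.DataFrame  # subject_id, w_hat, sigma_hat, loglik, placebo_magnitude
    scaled: pd.DataFrame = field(repr=False)
    sigma_summary: Mapping[str, float] = field(default_factory=dict)

    # -- basic accessors ------------------------------------------------
    @property
    def w_hat(self) -> pd.Series:
        return self.fits.set_index("subject_id")["w_hat"]

    @property
    def placebo_magnitudes(self) -> pd.Series:
        return self.fits.set_index("subject_id")["placebo_magnitude"]

    # -- cohort-level analyses ------------------------------------------
    def placebo_test(self) -> dict:
        """Paired one-tailed signed-rank test: red-cued vs green-cued high ratings."""
        reds, greens = [], []
        for _, sub in self.scaled.groupby("subject_id", sort=True):
            block = sub[
                (sub["stimulus_level"] == "high") & sub["cue"].isin(["red", "green"])
            ]
            placebo_block = block.loc[block["cue"] == "green", "block"].max()
            block = block[block["block"] == placebo_block]
            reds.append(block.loc[block["cue"] == "red", "vas_scaled"].mean())
            greens.append(block.loc[block["cue"] == "green", "vas_scaled"].mean())
        return signed_rank_one_tailed(reds, greens, alternative="greater")

    def expectation_correlation(self) -> dict:
        """Pearson correlation of fitted w with placebo magnitude (one-tailed)."""
        ok = self.fits.dropna(subset=["w_hat", "placebo_magnitude"])
        return explained_variance(ok["w_hat"], ok["placebo_magnitude"])

    # -- experiment-2 analyses ------------------------------------------
    def _mid_ratings(self) -> dict[object, np.ndarray]:
        mid = self.scaled[
            (self.scaled["block"] == 2) & (self.scaled["stimulus_level"] == "mid")
        ]
        if mid.empty:
            raise InputError("no mid-intensity uncued block in this design")
        return {
            subject: sub["vas_scaled"].to_numpy(dtype=float)
            for subject, sub in mid.groupby("subject_id", sort=True)
        }

    def clustering(self) -> pd.DataFrame:
        """Per-subject k-means clustering and bimodality of mid-stimulus ratings."""
        rows = []
        for subject, ratings in self._mid_ratings().items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bim = bimodality_test(ratings)
            cl = bim.clusters
            rows.append(
                {
                    "subject_id": subject,
                    "center_low": cl.centers[0],
                    "center_high": cl.centers[1],
                    "center_distance": cl.center_distance,
                    "separation_index": cl.separation_index,
                    "prob_bimodal": bim.posterior_prob_bimodal,
                    "bayes_factor_bimodal": bim.bayes_factor,
                    "degenerate": bim.degenerate,
                }
            )
        return pd.DataFrame(rows)

    def pooled_bimodality(self) -> dict:
        """Bimodality test on all subjects' scaled mid-stimulus ratings pooled."""
        pooled = np.concatenate(list(self._mid_ratings().values()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = bimodality_test(pooled)
        return {
            "posterior_prob_bimodal": res.posterior_prob_bimodal,
            "bayes_factor": res.bayes_factor,
            "n": int(pooled.size),
        }

    def model_comparison(self, *, w_step: float = 0.02) -> pd.DataFrame:
        """Per-subject posterior probabilities of the three candidate models."""
        rows = []
        for subject, sub in self.scaled.groupby("subject_id", sort=True):
            res = compare_models_subject(sub, self.model.params, w_step=w_step)
            row = {"subject_id": subject, "degenerate": res["degenerate"]}
            if res["scores"] is not None:
                for score in res["scores"]:
                    row[f"posterior_{score.model}"] = score.posterior
                    row[f"loglik_{score.model}"] = score.loglik
                row["best_model"] = max(res["scores"], key=lambda s: s.posterior).model
            else:
                row["best_model"] = None
            rows.append(row)
        return pd.DataFrame(rows)

    def correlation_table(self) -> pd.DataFrame:
        """Correlations of placebo size and fitted w with the clustering measures.

        Rows: placebo magnitude and w-hat; columns: cluster-center distance,
        separation index, bimodality probability. Each cell holds Pearson r
        and its one-tailed P (positive alternative).
        """
        cl = self.clustering().set_index("subject_id")
        fits = self.fits.set_index("subject_id").loc[cl.index]
        rows = {}
        for row_name, values in (
            ("placebo_size", fits["placebo_magnitude"]),
            ("expectation_w", fits["w_hat"]),
        ):
            cells = {}
            for col in ("center_distance", "separation_index", "prob_bimodal"):
                res = pearson_one_tailed(values.to_numpy(), cl[col].to_numpy())
                cells[f"{col}_r"] = res["r"]
                cells[f"{col}_P"] = res["P"]
            rows[row_name] = cells
        return pd.DataFrame(rows).T

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        """Plain-text cohort summary in the spirit of a regression results table."""
        lines = []
        n = self.fits["subject_id"].nunique()
        lines.append("Placebo conditioning experiment — fBD observer fit")
        lines.append("=" * 58)
        lines.append(f"subjects: {n}    trials: {len(self.model.data)}")
        p = self.model.params
        lines.append(
            f"fixed params: sigma_prior={p.sigma_prior} sd_nociceptor={p.sd_nociceptor} "
            f"sigma_rating={p.sigma_rating} anchors=({p.s_low}, {p.s_mid}, {p.s_high})"
        )
        w = self.fits["w_hat"].dropna()
        lines.append(
            f"w_hat: mean={w.mean():.3f}  sd={w.std(ddof=1):.3f}  "
            f"range=[{w.min():.2f}, {w.max():.2f}]"
        )
        if np.isfinite(self.sigma_summary.get("sigma_mean", np.nan)):
            lines.append(
                f"sigma_hat: mean={self.sigma_summary['sigma_mean']:.2f} "
                f"sd={self.sigma_summary['sigma_sd']:.2f}"
            )
        mag = self.fits["placebo_magnitude"].dropna()
        lines.append(f"placebo magnitude (%): mean={mag.mean():.2f}  sd={mag.std(ddof=1):.2f}")
        try:
            test = self.placebo_test()
            lines.append(
                f"signed-rank red>green: W={test['statistic']:.1f} "
                f"P(one-tailed)={test['P_one_tailed']:.2e}"
            )
        except Exception:  # cohort without a placebo block
            pass
        try:
            corr = self.expectation_correlation()
            lines.append(
                f"corr(w_hat, placebo): r={corr['r']:.3f} P={corr['P_one_tailed']:.2e} "
                f"residual variance={corr['residual_variance_percent']:.1f}%"
            )
        except Exception:
            pass
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_expectation_vs_placebo(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.fits["w_hat"], self.fits["placebo_magnitude"], s=18)
        ax.set_xlabel("fitted expectation weight $\\hat{w}$")
        ax.set_ylabel("placebo magnitude (%)")
        try:
            corr = self.expectation_correlation()
            ax.set_title(f"r = {corr['r']:.2f}")
        except Exception:
            pass
        return ax
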