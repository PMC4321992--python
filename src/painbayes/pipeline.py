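"""End-to-end replication on synthetic cohorts.

``run_replication`` executes the whole analysis chain on freshly simulated
cohorts of the two experimental designs: simulate -> scale -> fit (sigma
jointly with w on the first experiment, w per subject on the placebo blocks)
-> cohort placebo test -> model comparison on the held-out uncued block ->
clustering/bimodality -> correlation table. Every number in the report is a
deterministic function of the config and the master seed, both of which are
stamped into the report.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, config_hash
from .exceptions import PainBayesError
from .model import PlaceboExperiment
from .observer import CueCondition, prediction_surface
from .simulate import CohortSpec, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_replication", "predict_surfaces"]


def _stage(name: str):
    logger.info("stage: %s", name)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def run_replication(
    config: AnalysisConfig | None = None,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full synthetic replication; optionally write all artifacts.

    Returns the report dictionary (also written as ``report.json`` when
    ``out_dir`` is given, alongside ``ratings/``, ``fits/``, ``comparison/``
    and ``predictions/`` subdirectories).
    """
    if config is None:
        config = AnalysisConfig()
    report: dict = {
        "provenance": {
            "master_seed": int(master_seed),
            "config_hash": config_hash(config),
            "config": config.to_dict(),
        }
    }
    root = np.random.SeedSequence(master_seed)
    seed1, seed2 = (int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2))
    base = config.params

    try:
        _stage("simulate")
        spec1 = CohortSpec(
            n_subjects=config.cohort1.n_subjects, experiment=1, w=config.cohort1.w,
            base_params=base, master_seed=seed1,
        )
        spec2 = CohortSpec(
            n_subjects=config.cohort2.n_subjects, experiment=2, w=config.cohort2.w,
            base_params=base, master_seed=seed2,
        )
        records1, truth1 = simulate_cohort(spec1, config.grid)
        records2, truth2 = simulate_cohort(spec2, config.grid)

        _stage("fit experiment 1 (sigma jointly with w)")
        exp1 = PlaceboExperiment(records1, base, config.grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res1 = exp1.fit(estimate_sigma=True)
        report["experiment1"] = {
            "n_subjects": config.cohort1.n_subjects,
            "sigma_hat_mean": res1.sigma_summary.get("sigma_mean"),
            "sigma_hat_sd": res1.sigma_summary.get("sigma_sd"),
            "placebo_magnitude_mean": float(res1.placebo_magnitudes.mean()),
            "placebo_signed_rank": res1.placebo_test(),
            "expectation_correlation": res1.expectation_correlation(),
        }

        _stage("fit experiment 2 (w per subject)")
        exp2 = PlaceboExperiment(records2, base, config.grid)
        res2 = exp2.fit(w_step=0.01)
        report["experiment2"] = {
            "n_subjects": config.cohort2.n_subjects,
            "w_hat_mean": float(res2.w_hat.mean()),
            "placebo_magnitude_mean": float(res2.placebo_magnitudes.mean()),
            "placebo_signed_rank": res2.placebo_test(),
            "expectation_correlation": res2.expectation_correlation(),
        }

        _stage("model comparison on held-out uncued block")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comparison = res2.model_comparison()
        wins = comparison["best_model"].value_counts().to_dict()
        report["model_comparison"] = {
            "wins": {str(k): int(v) for k, v in wins.items()},
            "mean_posteriors": {
                m: float(comparison[f"posterior_{m}"].mean())
                for m in ("no_learn", "simple_bayes", "fbd")
                if f"posterior_{m}" in comparison
            },
        }

        _stage("clustering and bimodality")
        clustering = res2.clustering()
        pooled = res2.pooled_bimodality()
        corr = res2.correlation_table()
        report["clustering"] = {
            "mean_center_distance": float(clustering["center_distance"].mean()),
            "mean_separation_index": float(clustering["separation_index"].mean()),
            "mean_prob_bimodal": float(clustering["prob_bimodal"].mean()),
            "pooled_bimodality": pooled,
            "correlation_table": {
                row: {col: float(corr.loc[row, col]) for col in corr.columns}
                for row in corr.index
            },
        }
    except PainBayesError as err:
        logger.error("pipeline aborted: %s", err)
        report["error"] = str(err)
        raise

    if out_dir is not None:
        out = Path(out_dir)
        for sub in ("ratings", "fits", "predictions", "comparison"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        res1.scaled.to_csv(out / "ratings" / "experiment1.csv", index=False)
        res2.scaled.to_csv(out / "ratings" / "experiment2.csv", index=False)
        truth1.to_csv(out / "ratings" / "truth1.csv", index=False)
        truth2.to_csv(out / "ratings" / "truth2.csv", index=False)
        res1.fits.to_csv(out / "fits" / "experiment1.csv", index=False)
        res2.fits.to_csv(out / "fits" / "experiment2.csv", index=False)
        comparison.to_csv(out / "comparison" / "model_posteriors.csv", index=False)
        clustering.to_csv(out / "comparison" / "clustering.csv", index=False)
        predict_surfaces(config, out / "predictions")
        (out / "report.json").write_text(json.dumps(_to_jsonable(report), indent=2))
    return report


def predict_surfaces(config: AnalysisConfig | None = None, out_dir: str | Path | None = None):
    """Rating-prediction surfaces for the pre-conditioning state and each cue.

    Returns the four surfaces; when ``out_dir`` is given, writes each as a
    CSV matrix (stimulus rows x rating columns, grid values as headers).
    """
    if config is None:
        config = AnalysisConfig()
    cases = {
        "pre_conditioning": (0.0, CueCondition.NONE),
        "post_no_cue": (config.params.w, CueCondition.NONE),
        "post_green": (config.params.w, CueCondition.GREEN),
        "post_red": (config.params.w, CueCondition.RED),
    }
    surfaces = {}
    for name, (w, cue) in cases.items():
        surf = prediction_surface(cue, config.params.with_w(w), config.grid)
        surfaces[name] = surf
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            surf.to_frame().to_csv(out / f"{name}.csv")
            pd.DataFrame(
                {"stimulus": surf.grid.points, "most_probable_rating": surf.ridge}
            ).to_csv(out / f"{name}_ridge.csv", index=False)
    return surfaces
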