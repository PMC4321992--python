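"""Configuration loading for the analysis pipeline.

A config file (YAML or JSON — YAML is a superset) has three optional
sections, all with sensible defaults::

    grid:    {lo: 0, hi: 100, step: 0.5}
    params:  {w: 0.9, sigma_prior: 5.7, sd_nociceptor: 10.0,
              sigma_rating: 4.0, s_low: 35, s_mid: 50, s_high: 65}
    cohorts:
      experiment1: {n_subjects: 24, w: [0.0, 1.0]}
      experiment2: {n_subjects: 31, w: [0.0, 1.0]}

``params.w`` is the exploration value used for prediction surfaces; cohort
``w`` entries may be a number (homogeneous) or a two-element [lo, hi] range
(uniform across subjects).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import InputError
from .grid import IntensityGrid
from .observer import SubjectParams

__all__ = ["CohortConfig", "AnalysisConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int
    w: float | tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InputError("cohort needs at least one subject")


@dataclass(frozen=True)
class AnalysisConfig:
    grid: IntensityGrid = field(default_factory=IntensityGrid)
    params: SubjectParams = field(default_factory=lambda: SubjectParams(w=0.9))
    cohort1: CohortConfig = field(default_factory=lambda: CohortConfig(n_subjects=24))
    cohort2: CohortConfig = field(default_factory=lambda: CohortConfig(n_subjects=31))

    def to_dict(self) -> dict:
        return {
            "grid": dataclasses.asdict(self.grid),
            "params": dataclasses.asdict(self.params),
            "cohorts": {
                "experiment1": {
                    "n_subjects": self.cohort1.n_subjects,
                    "w": list(self.cohort1.w)
                    if isinstance(self.cohort1.w, tuple)
                    else self.cohort1.w,
                },
                "experiment2": {
                    "n_subjects": self.cohort2.n_subjects,
                    "w": list(self.cohort2.w)
                    if isinstance(self.cohort2.w, tuple)
                    else self.cohort2.w,
                },
            },
        }


def _parse_w(value) -> float | tuple[float, float]:
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return (float(value[0]), float(value[1]))
    raise InputError(f"cohort w must be a number or a [lo, hi] pair, got {value!r}")


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a YAML/JSON config; missing sections fall back to the defaults."""
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return AnalysisConfig()
    if not isinstance(raw, dict):
        raise InputError(f"config root must be a mapping, got {type(raw).__name__}")
    grid = IntensityGrid(**raw.get("grid", {}))
    params_dict = {"w": 0.9, **raw.get("params", {})}
    params = SubjectParams(**params_dict)
    cohorts = raw.get("cohorts", {})

    def cohort(section: str, default_n: int) -> CohortConfig:
        sec = cohorts.get(section, {})
        return CohortConfig(
            n_subjects=int(sec.get("n_subjects", default_n)),
            w=_parse_w(sec.get("w", [0.0, 1.0])),
        )

    return AnalysisConfig(
        grid=grid,
        params=params,
        cohort1=cohort("experiment1", 24),
        cohort2=cohort("experiment2", 31),
    )


def config_hash(config: AnalysisConfig) -> str:
    """Stable SHA-256 of the canonical JSON form (provenance stamp)."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
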