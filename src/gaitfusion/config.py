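"""Run configuration shared by every pipeline stage.

A :class:`RunConfig` collects every tunable knob of the pipeline —
normalized-cycle length, gait-event detection settings, sample-entropy
parameters, cycle selection bounds, and the cross-validation design — so a
whole run is a pure function of (inputs, config, seed).  Configs can be
loaded from a YAML file; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("gaitfusion")

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Effective configuration for a pipeline run.

    Attributes
    ----------
    n_cycle_points:
        Samples per time-normalized gait cycle (0–100% of the cycle).
        101 points (1% steps) is the biomechanics convention.
    onset_prominence_frac:
        Heel-strike onset rule: minimum rise (as a fraction of the ankle
        trace's range of motion) required between a plantarflexion trough
        and the derivative zero-crossing accepted as the next heel strike.
    smooth_window:
        Moving-average width (samples) used *only* inside event detection.
    min_cycle_separation_frac:
        Minimum separation between toe-off troughs, as a fraction of the
        median inter-trough interval, to suppress double peaks.
    sampen_m, sampen_r_frac:
        Sample-entropy embedding dimension and tolerance (fraction of the
        series SD, or degrees when ``sampen_r_mode`` is ``"absolute"``).
    sampen_r_mode:
        ``"sd_relative"`` (default) or ``"absolute"``.
    sampen_input:
        ``"concatenated"`` — one entropy per subject-joint on the
        concatenated selected cycles (default) — or ``"per_cycle_mean"``.
    cycle_k_min, cycle_k_max:
        Number of gait cycles randomly retained per subject.
    aggregate:
        Per-subject cyclogram-feature aggregation across cycles:
        ``"mean"`` (default) or ``"median"``.
    n_top_features:
        ANOVA-F feature-selection size inside each training fold.
    outer_folds, inner_folds:
        Nested stratified cross-validation design.
    rf_search_iters:
        Random-search draws for the random-forest hyperparameter search.
    rf_search_mode:
        ``"random"`` (default) or ``"grid"``.
    bootstrap_B:
        Bootstrap resamples for AUC confidence intervals.
    ancova_ss_type:
        Sums-of-squares type for the ANCOVA group effect (2 default).
    alpha, pairwise_alpha:
        Omnibus significance level and the Bonferroni-corrected pairwise
        threshold (0.05/3 reported as 0.017).
    seed:
        Master seed; every random draw in a run derives from it.
    """

    n_cycle_points: int = 101
    onset_prominence_frac: float = 0.05
    smooth_window: int = 5
    min_cycle_separation_frac: float = 0.5
    sampen_m: int = 2
    sampen_r_frac: float = 0.1
    sampen_r_mode: str = "sd_relative"
    sampen_input: str = "concatenated"
    cycle_k_min: int = 3
    cycle_k_max: int = 5
    aggregate: str = "mean"
    n_top_features: int = 10
    outer_folds: int = 5
    inner_folds: int = 3
    rf_search_iters: int = 20
    rf_search_mode: str = "random"
    bootstrap_B: int = 1000
    ancova_ss_type: int = 2
    alpha: float = 0.05
    pairwise_alpha: float = 0.017
    seed: int = 0
    source_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_cycle_points < 4:
            raise ValueError("n_cycle_points must be >= 4")
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        if self.sampen_r_frac <= 0:
            raise ValueError("sampen_r_frac must be > 0")
        if self.sampen_r_mode not in ("sd_relative", "absolute"):
            raise ValueError(f"unknown sampen_r_mode {self.sampen_r_mode!r}")
        if self.sampen_input not in ("concatenated", "per_cycle_mean"):
            raise ValueError(f"unknown sampen_input {self.sampen_input!r}")
        if self.aggregate not in ("mean", "median"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        if not 1 <= self.cycle_k_min <= self.cycle_k_max:
            raise ValueError("need 1 <= cycle_k_min <= cycle_k_max")
        if self.ancova_ss_type not in (1, 2, 3):
            raise ValueError("ancova_ss_type must be 1, 2 or 3")
        if self.rf_search_mode not in ("random", "grid"):
            raise ValueError(f"unknown rf_search_mode {self.rf_search_mode!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["config_schema_version"] = CONFIG_SCHEMA_VERSION
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config file, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        raw.pop("config_schema_version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw, source_path=str(path))


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with a compact format."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
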