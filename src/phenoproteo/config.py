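"""Configuration objects for cohort simulation and pipeline parameters.

Defaults emulate a population-based heart-failure cohort profiled on a
~7000-plex aptamer panel: three latent phenogroups of unequal size, blocks
of correlated protein features, ~9% multiplicative technical noise, and
right-censored all-cause mortality followed over roughly 14 years with
phenogroup-graded hazards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """A cohort or pipeline configuration violates its invariants."""


@dataclass
class CovariateSpec:
    """Distribution and per-group trend of each clinical covariate.

    Continuous covariates are Gaussian with a linear trend across group
    index (group ``g`` of ``k`` receives ``trend * (g - (k-1)/2)``), so the
    worst group is older, has lower eGFR, higher log-NT-proBNP and higher
    risk score. Binary covariates are Bernoulli; atrial fibrillation gets a
    per-group prevalence trend, ejection fraction does not (phenogroups in
    this design are EF-independent).
    """

    age_mean: float = 76.0
    age_sd: float = 10.0
    age_trend: float = 3.0  # years per group index step
    sex_p_female: float = 0.48
    egfr_mean: float = 60.0
    egfr_sd: float = 18.0
    egfr_trend: float = -10.0  # mL/min/1.73m2 per step; worst group lowest
    log_ntprobnp_mean: float = 7.3  # ln pg/mL, median ~1500 pg/mL
    log_ntprobnp_sd: float = 1.1
    log_ntprobnp_trend: float = 0.6
    maggic_mean: float = 22.0
    maggic_sd: float = 6.0
    maggic_trend: float = 2.5
    ef_lt40_p: float = 0.31
    afib_p: float = 0.35
    afib_trend: float = 0.07
    hf_duration_ge18mo_p: float = 0.5


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic proteomics cohort.

    ``effect_size`` is the SD of group mean shifts applied to the shared
    latent factor of each informative module, in within-group SD units of
    the factor; members inherit the shift attenuated by
    ``sqrt(within_module_corr)``.
    """

    n_samples: int = 1351
    n_features: int = 1000
    n_groups: int = 3
    group_proportions: tuple[float, ...] = (0.45, 0.245, 0.305)
    n_modules: int = 40
    module_size_range: tuple[int, int] = (4, 15)
    within_module_corr: float = 0.8
    n_informative_modules: int = 20
    effect_size: float = 2.0
    technical_cv: float = 0.09
    n_qc_fail_samples: int = 0
    hazard_scale_per_group: tuple[float, ...] = (0.10, 0.15, 0.22)
    weibull_shape: float = 1.0  # 1.0 = exponential
    censoring_rate: float = 0.02
    followup_horizon: float = 14.0
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_features < 1:
            raise ConfigurationError("n_samples and n_features must be positive")
        props = np.asarray(self.group_proportions, dtype=float)
        if len(props) != self.n_groups:
            raise ConfigurationError(
                f"group_proportions length {len(props)} != n_groups {self.n_groups}"
            )
        if abs(props.sum() - 1.0) > 1e-9 or (props <= 0).any():
            raise ConfigurationError(
                "group_proportions must be strictly positive and sum to 1"
            )
        lo, hi = self.module_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid module_size_range")
        if self.n_modules * hi > 0 and self.n_modules * lo > self.n_features:
            raise ConfigurationError(
                f"module packing infeasible: {self.n_modules} modules of size "
                f">= {lo} exceed {self.n_features} features"
            )
        if not (0.0 <= self.within_module_corr < 1.0):
            raise ConfigurationError("within_module_corr must be in [0, 1)")
        if self.n_informative_modules > self.n_modules:
            raise ConfigurationError("n_informative_modules > n_modules")
        hz = np.asarray(self.hazard_scale_per_group, dtype=float)
        if len(hz) != self.n_groups:
            raise ConfigurationError("hazard_scale_per_group length != n_groups")
        if (hz <= 0).any():
            raise ConfigurationError("hazards must be strictly positive")
        if self.censoring_rate < 0 or self.followup_horizon <= 0:
            raise ConfigurationError("invalid censoring parameters")
        if self.technical_cv < 0:
            raise ConfigurationError("technical_cv must be >= 0")
        if self.n_qc_fail_samples >= self.n_samples:
            raise ConfigurationError("n_qc_fail_samples must be < n_samples")
        if self.weibull_shape <= 0:
            raise ConfigurationError("weibull_shape must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "covariate_spec" in d and isinstance(d["covariate_spec"], dict):
            d["covariate_spec"] = CovariateSpec(**d["covariate_spec"])
        for key in ("group_proportions", "module_size_range", "hazard_scale_per_group"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Load from a YAML or JSON file (JSON is a YAML subset)."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineParams:
    """Tunable parameters of the phenomapping pipeline itself."""

    mad_fraction: float = 0.3
    corr_threshold: float = 0.7
    corr_method: str = "spearman"
    hub_rule: str = "max_connectivity"
    n_reduction_rounds: int = 1
    k_range: tuple[int, int] = (2, 8)  # inclusive
    n_resamples: int = 1000
    subsample_fraction: float = 0.8
    n_init: int = 50
    scale_factor_bounds: tuple[float, float] = (0.4, 2.5)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)
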