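"""Simulation configuration.

The defaults describe an ADNI-like cohort: four groups (amyloid-negative
controls, and amyloid-positive cognitively normal / MCI / dementia
subjects), with group sizes, covariate distributions, annual cognitive
change-rate means/SDs per domain, and global tau-PET levels taken from the
published cohort description. An A05-like variant (smaller trial cohort,
no education variable, compressed change-rate scale) is provided as an
alternative constructor.

Latent tau burden is a per-domain lognormal with a group-specific mean and
a shared cross-domain correlation; each domain's cognitive slope couples to
the burden in that domain only. The configured change-rate SDs are treated
as the *total* per-group SD: the generator subtracts the analytically known
coupling-induced variance to obtain the residual slope-noise SD, so that
generated group-level change-rate means and SDs land on their targets.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

GROUPS = ("CN_NEG", "CN_POS", "MCI_POS", "DEM_POS")
DOMAINS = ("MEM", "LAN", "EF", "VS")


def _per_group(cn_neg, cn_pos, mci, dem):
    return dict(zip(GROUPS, (cn_neg, cn_pos, mci, dem)))


def _per_domain(mem, lan, ef, vs):
    return dict(zip(DOMAINS, (mem, lan, ef, vs)))


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    # cohort structure
    counts: dict = field(default_factory=lambda: _per_group(121, 62, 53, 25))
    grid_dims: tuple = (20, 20, 20)
    seed: int = 0
    subject_prefix: str = "ADNI"

    # covariates
    age_mean: dict = field(default_factory=lambda: _per_group(73.61, 75.85, 75.87, 76.60))
    age_sd: dict = field(default_factory=lambda: _per_group(7.05, 7.08, 7.13, 10.21))
    age_range: tuple = (50.0, 100.0)
    female_frac: dict = field(
        default_factory=lambda: _per_group(69 / 121, 35 / 62, 22 / 53, 12 / 25)
    )
    apoe4_frac: dict = field(
        default_factory=lambda: _per_group(33 / 121, 34 / 62, 31 / 53, 16 / 25)
    )
    education_mean: dict = field(default_factory=lambda: _per_group(16.69, 16.87, 15.89, 15.84))
    education_sd: dict = field(default_factory=lambda: _per_group(2.46, 2.28, 2.80, 2.49))
    #: A05-style cohorts set this False: education is generated but dropped
    #: from downstream covariate sets.
    education_available: bool = True

    # latent tau burden (per-domain lognormal, shared log-scale SD)
    burden_group_mean: dict = field(default_factory=lambda: _per_group(0.05, 0.38, 1.13, 3.0))
    burden_log_sigma: float = 0.8
    burden_rho: float = 0.5
    #: ceiling on the latent burden: tracer signal saturates, and an
    #: uncapped lognormal tail would put all leverage on one subject
    burden_cap: float = 8.0

    # SUVR image model
    suvr_neg_mean: float = 1.05
    suvr_neg_sd: float = 0.07
    elevation_per_burden: float = 0.133
    #: per-voxel elevation gain ~ Uniform(1-h, 1+h), fixed across subjects:
    #: tau deposition intensity varies spatially, which keeps the ROI-mean
    #: positivity probability graded rather than step-like in burden
    elevation_heterogeneity: float = 0.6
    suvr_floor: float = 0.2

    # cognition model: slope mean/SD per group x domain (targets),
    # coupling per domain, baseline score distribution, visit schedule
    slope_mean: dict = field(
        default_factory=lambda: {
            "MEM": _per_group(0.045, 0.026, -0.084, -0.179),
            "LAN": _per_group(-0.044, -0.047, -0.084, -0.132),
            "EF": _per_group(-0.065, -0.086, -0.095, -0.110),
            "VS": _per_group(-0.004, -0.006, -0.009, -0.022),
        }
    )
    slope_sd: dict = field(
        default_factory=lambda: {
            "MEM": _per_group(0.064, 0.071, 0.075, 0.081),
            "LAN": _per_group(0.028, 0.030, 0.037, 0.055),
            "EF": _per_group(0.035, 0.034, 0.031, 0.028),
            "VS": _per_group(0.007, 0.008, 0.010, 0.015),
        }
    )
    #: slope change per unit latent burden; negative: more tau, faster decline
    coupling: dict = field(default_factory=lambda: _per_domain(-0.049, -0.034, -0.018, -0.010))
    baseline_mean: dict = field(
        default_factory=lambda: {
            "MEM": _per_group(0.6, 0.4, -0.3, -1.0),
            "LAN": _per_group(0.3, 0.2, -0.3, -0.8),
            "EF": _per_group(0.4, 0.2, -0.3, -0.9),
            "VS": _per_group(0.06, 0.04, -0.04, -0.15),
        }
    )
    baseline_sd: dict = field(default_factory=lambda: _per_domain(0.6, 0.4, 0.5, 0.10))
    #: composite measurement noise per visit; small enough that mixed-model
    #: estimated rates keep the Table-1-magnitude spread the targets describe
    score_residual_sd: dict = field(default_factory=lambda: _per_domain(0.05, 0.03, 0.03, 0.004))
    visit_times: tuple = (0.0, 0.75, 1.5)
    dropout_last_visit: float = 0.35

    # ------------------------------------------------------------------
    def validate(self) -> "SimulationConfig":
        for g in GROUPS:
            if self.counts.get(g, 0) < 0:
                raise ConfigError(f"negative count for group {g}")
            if self.age_sd[g] <= 0 or self.education_sd[g] <= 0:
                raise ConfigError("covariate SDs must be positive")
            if self.burden_group_mean[g] <= 0:
                raise ConfigError("burden group means must be positive")
        for d in DOMAINS:
            for g in GROUPS:
                if self.slope_sd[d][g] <= 0:
                    raise ConfigError("slope SDs must be positive")
            if self.score_residual_sd[d] < 0:
                raise ConfigError("score residual SD must be non-negative")
        if len(self.grid_dims) != 3 or any(int(n) < 8 for n in self.grid_dims):
            raise ConfigError("grid_dims must be three integers >= 8")
        if not (0.0 <= self.dropout_last_visit <= 1.0):
            raise ConfigError("dropout_last_visit must lie in [0, 1]")
        if len(self.visit_times) < 2 or self.visit_times[0] != 0.0:
            raise ConfigError("visit schedule must start at 0 and have >= 2 visits")
        if not (0.0 <= self.burden_rho < 1.0):
            raise ConfigError("burden_rho must lie in [0, 1)")
        if self.burden_log_sigma <= 0 or self.suvr_neg_sd <= 0:
            raise ConfigError("scale parameters must be positive")
        return self

    # analytic moments of the lognormal burden -------------------------
    def burden_log_mu(self, group: str) -> float:
        """Location parameter giving the configured group mean burden."""
        return math.log(self.burden_group_mean[group]) - 0.5 * self.burden_log_sigma**2

    def burden_var(self, group: str) -> float:
        s2 = self.burden_log_sigma**2
        return (math.exp(s2) - 1.0) * self.burden_group_mean[group] ** 2

    def residual_slope_sd(self, domain: str, group: str) -> float:
        """Slope-noise SD after removing coupling-induced variance.

        Floored at 20% of the configured total SD so a strong coupling can
        never demand a negative residual variance.
        """
        total = self.slope_sd[domain][group]
        coupled = self.coupling[domain] ** 2 * self.burden_var(group)
        return math.sqrt(max(total**2 - coupled, (0.2 * total) ** 2))

    # (de)serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        if "grid_dims" in kwargs:
            kwargs["grid_dims"] = tuple(kwargs["grid_dims"])
        if "visit_times" in kwargs:
            kwargs["visit_times"] = tuple(kwargs["visit_times"])
        if "age_range" in kwargs:
            kwargs["age_range"] = tuple(kwargs["age_range"])
        return cls(**kwargs).validate()

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # ------------------------------------------------------------------
    @classmethod
    def adni_like(cls, **overrides) -> "SimulationConfig":
        """Discovery-cohort defaults (the dataclass defaults)."""
        return cls(**overrides).validate()

    @classmethod
    def a05_like(cls, **overrides) -> "SimulationConfig":
        """Validation-trial-like cohort: smaller, no education variable,
        compressed change-rate scale, near-complete 3-visit follow-up."""
        kwargs = dict(
            counts=_per_group(46, 5, 35, 25),
            subject_prefix="A05",
            age_mean=_per_group(67.41, 77.8, 72.06, 76.04),
            age_sd=_per_group(10.19, 7.01, 8.77, 9.34),
            female_frac=_per_group(20 / 46, 2 / 5, 16 / 35, 14 / 25),
            apoe4_frac=_per_group(9 / 46, 2 / 5, 17 / 33, 18 / 25),
            education_available=False,
            burden_group_mean=_per_group(0.05, 0.06, 1.6, 2.7),
            suvr_neg_mean=1.00,
            suvr_neg_sd=0.08,
            slope_mean={
                "MEM": _per_group(0.022, 0.015, -0.019, -0.038),
                "LAN": _per_group(-0.001, 0.009, -0.031, -0.070),
                "EF": _per_group(0.006, 0.009, -0.040, -0.077),
                "VS": _per_group(0.005, 0.0007, -0.032, -0.107),
            },
            slope_sd={
                "MEM": _per_group(0.027, 0.032, 0.026, 0.011),
                "LAN": _per_group(0.031, 0.018, 0.030, 0.049),
                "EF": _per_group(0.026, 0.010, 0.040, 0.048),
                "VS": _per_group(0.027, 0.021, 0.054, 0.097),
            },
            coupling=_per_domain(-0.004, -0.012, -0.012, -0.020),
            score_residual_sd=_per_domain(0.03, 0.03, 0.03, 0.03),
            visit_times=(0.0, 0.7, 1.4),
            dropout_last_visit=0.1,
        )
        kwargs.update(overrides)
        return cls(**kwargs).validate()
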