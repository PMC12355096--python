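"""Simulation and pipeline configuration.

The defaults encode the study conditions the synthetic cohort emulates:
a cancer cohort recruited at ages 40-71 (mean 60, SD 7), ~5.5% CHIP
prevalence and ~20.7% any-mCA prevalence at the mean age, age/smoking/
chemotherapy enrichment of clonal hematopoiesis, LOY negatively and LOX
positively associated with CHIP, a 2% VAF detection floor, and exponential
proportional-hazards event processes for five cardiovascular endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import yaml

ENDPOINTS = ("incident_cvd", "incident_cad", "cv_death", "cad_death", "any_death")

#: four-category clonal hematopoiesis exposure
EXPOSURE4 = ("no_ch", "chip_only", "mca_only", "both")

PANEL_GENES = (
    "ASXL1", "CBL", "DNMT3A", "GNAS", "GNB1", "JAK2",
    "PPM1D", "SF3B1", "SRSF2", "TET2", "TP53",
)


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class HazardConfig:
    """Exponential baseline hazards and true log-HRs for event generation.

    ``exposure_log_hr`` maps endpoint -> {chip_only, mca_only, both}; these
    are the truth values recovered by the survival parameter-recovery tests.
    Defaults sit near the published adjusted hazard ratios for the
    four-category CH exposure (e.g. CHIP only vs no CH, incident CVD,
    HR 1.082).  ``covariate_log_hr`` maps endpoint -> covariate effects.
    Rates are per person-year; the censoring horizon is administrative.
    """

    baseline_rate: Dict[str, float] = field(default_factory=lambda: {
        "incident_cvd": 0.055,
        "incident_cad": 0.011,
        "cv_death": 0.0013,
        "cad_death": 0.0006,
        "any_death": 0.021,
    })
    exposure_log_hr: Dict[str, Dict[str, float]] = field(default_factory=lambda: {
        "incident_cvd": {"chip_only": math.log(1.082), "mca_only": math.log(0.995),
                         "both": math.log(1.048)},
        "incident_cad": {"chip_only": math.log(1.110), "mca_only": math.log(1.031),
                         "both": math.log(1.069)},
        "cv_death": {"chip_only": math.log(1.073), "mca_only": math.log(1.148),
                     "both": math.log(1.090)},
        "cad_death": {"chip_only": math.log(0.798), "mca_only": math.log(1.363),
                      "both": math.log(1.210)},
        "any_death": {"chip_only": math.log(1.305), "mca_only": math.log(1.068),
                      "both": math.log(1.406)},
    })
    covariate_log_hr: Dict[str, Dict[str, float]] = field(default_factory=lambda: {
        ep: {
            "age_baseline": 0.05,
            "sex_M": 0.30,
            "smoking_current": 0.50,
            "smoking_previous": 0.15,
            "chemo": 0.30,
            "radio": 0.08,
            "prevalent_cvd": 0.60,
        }
        for ep in ENDPOINTS
    })
    censoring_horizon_years: float = 15.0

    def validate(self) -> None:
        for ep in ENDPOINTS:
            if ep not in self.baseline_rate:
                raise ConfigError(f"missing baseline rate for endpoint {ep!r}")
            if self.baseline_rate[ep] <= 0:
                raise ConfigError(f"baseline rate for {ep!r} must be > 0")
            for cat in ("chip_only", "mca_only", "both"):
                if cat not in self.exposure_log_hr.get(ep, {}):
                    raise ConfigError(f"missing exposure log-HR {cat!r} for {ep!r}")
        if self.censoring_horizon_years <= 0:
            raise ConfigError("censoring horizon must be > 0")


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_participants: int = 20_000
    seed: int = 0

    # demographics (cohort marginals: mean age 60, SD 7, range 40-71)
    age_range: Tuple[float, float] = (40.0, 71.0)
    age_mean: float = 60.0
    age_sd: float = 7.0
    female_fraction: float = 0.542
    smoking_probs: Dict[str, float] = field(default_factory=lambda: {
        "never": 0.488, "previous": 0.395, "current": 0.111, "unknown": 0.006,
    })
    chemo_prob: float = 0.233
    radio_prob: float = 0.063
    prevalent_cvd_prob: float = 0.226
    tert_maf: float = 0.3

    # CHIP carriage: logistic model in (age - age_mean), smoking, chemo
    chip_prevalence_at_mean_age: float = 0.055
    chip_log_or_per_year_age: float = math.log(1.080)
    chip_log_or_current_smoker: float = 0.380   # current vs never, ~1/0.684
    chip_log_or_previous_smoker: float = 0.111  # previous vs never, ~0.764/0.684
    chip_log_or_chemo: float = math.log(1.258)

    # mCA carriage: LOY (men), LOX (women), autosomal components
    mca_prevalence_at_mean_age: float = 0.207
    mca_log_or_per_year_age: float = math.log(1.095)
    mca_log_or_current_smoker: float = 0.20
    mca_log_or_chemo: float = 0.15
    loy_prevalence_males: float = 0.288
    lox_prevalence_females: float = 0.062
    autosomal_mca_prevalence: float = 0.055
    loy_chip_log_or: float = math.log(0.652)
    lox_chip_log_or: float = math.log(1.242)

    # clone-size distributions
    vaf_floor: float = 0.02
    vaf_beta: Tuple[float, float] = (1.0, 6.0)       # truncated at vaf_floor
    cell_fraction_beta: Tuple[float, float] = (0.4, 6.74)

    # mutation multiplicity among carriers (1 / 2 / >=3 split 84.4/8.6/7.0)
    mutation_count_probs: Dict[int, float] = field(default_factory=lambda: {
        1: 0.844, 2: 0.086, 3: 0.056, 4: 0.014,
    })

    # filter-cascade exercise
    generate_read_evidence: bool = True
    decoy_fraction: float = 0.03
    recurrent_decoy_fraction: float = 0.004

    # exclusion-rule exercise
    relative_pair_fraction: float = 0.01
    sex_discordant_fraction: float = 0.002
    hematologic_fraction: float = 0.006

    prevalent_cancer_fraction: float = 0.5
    cancer_type_frequencies: Dict[str, float] = field(default_factory=lambda: {
        "breast": 0.25, "prostate": 0.18, "colorectal": 0.12, "lung": 0.08,
        "melanoma": 0.08, "uterus": 0.05, "kidney": 0.05, "bladder": 0.05,
        "rectal": 0.05, "other": 0.09,
    })

    hazard: HazardConfig = field(default_factory=HazardConfig)

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be a positive integer")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError("age_range must satisfy min < max")
        for name in ("chip_prevalence_at_mean_age", "mca_prevalence_at_mean_age",
                     "female_fraction", "chemo_prob", "radio_prob",
                     "prevalent_cvd_prob", "decoy_fraction",
                     "recurrent_decoy_fraction", "loy_prevalence_males",
                     "lox_prevalence_females", "autosomal_mca_prevalence",
                     "prevalent_cancer_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.vaf_floor < 0.02:
            raise ConfigError("vaf_floor below the 2% CHIP detection threshold")
        if abs(sum(self.smoking_probs.values()) - 1.0) > 1e-6:
            raise ConfigError("smoking_probs must sum to 1")
        if abs(sum(self.mutation_count_probs.values()) - 1.0) > 1e-6:
            raise ConfigError("mutation_count_probs must sum to 1")
        if abs(sum(self.cancer_type_frequencies.values()) - 1.0) > 1e-6:
            raise ConfigError("cancer_type_frequencies must sum to 1")
        self.hazard.validate()

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "hazard" in d and isinstance(d["hazard"], dict):
            h = dict(d["hazard"])
            d["hazard"] = HazardConfig(**h)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "vaf_beta" in d:
            d["vaf_beta"] = tuple(d["vaf_beta"])
        if "cell_fraction_beta" in d:
            d["cell_fraction_beta"] = tuple(d["cell_fraction_beta"])
        if "mutation_count_probs" in d:
            d["mutation_count_probs"] = {int(k): float(v)
                                         for k, v in d["mutation_count_probs"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(d)
        if seed is not None:
            cfg.seed = seed
        return cfg
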