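"""Synthetic spiked-replicate validation experiments.

Emulates the data-generating process behind an intra-laboratory validation
of a quantitative residue method: blank matrix spiked at a ladder of
concentrations, four replicates per day over three days, each day
accompanied by a matrix-matched calibration curve (analyte added to blank
extract immediately before injection) plus a solvent-standard curve.

Generative model for one analyte in one matrix
----------------------------------------------
* Matrix-matched response slope  b_MM = b_S * (1 + ME/100) with ME the true
  matrix effect in percent (signed: suppression < 0 < enhancement).
* Spiked-sample quantifier area at concentration c on day i, replicate j:

      A_ij = Rec * (a + b_MM * c) * (1 + d_i + e_ij)

  with day effect d_i ~ N(0, sigma_L), replicate effect e_ij ~ N(0, sigma_r),
  sigma_r = CV_r/100 and sigma_L = sqrt((CV_wR/100)^2 - sigma_r^2). The day
  effect is shared by all replicates of a day, emulating day-to-day drift of
  the LC-MS system; the replicate effect is the within-day (repeatability)
  scatter. Multiplicative noise gives a constant CV across the 150-fold
  concentration range, matching how precision is reported.
* Matrix-matched / solvent standards carry injection noise only (they skip
  the extraction, so no recovery loss and no day effect on the expectation).
* Blanks: max(0, N(0, blank_noise_sd)).
* Qualifier areas are the quantifier times the reference ion ratio times a
  small injection-like noise.

All randomness flows from ``SimulationConfig.seed``; the same seed yields a
bit-identical dataset.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import ConfigError

MEASUREMENT_COLUMNS = (
    "analyte",
    "matrix",
    "sample_kind",
    "level",
    "day",
    "replicate",
    "transition_rank",
    "area",
)

#: Spike ladders used by the validation design (ug/kg).
MUSCLE_LEVELS = (10.0, 33.0, 100.0, 150.0, 333.0, 1000.0, 1500.0)
MILK_LEVELS = (10.0, 33.0, 100.0, 150.0, 333.0)
#: Matrix-matched calibration ladder (ug/kg), blank added separately.
CALIBRATION_LEVELS = (2.0, 10.0, 33.0, 100.0, 150.0)
#: Beta-lactams additionally checked at half the milk MRL.
HALF_MRL_MILK_LEVEL = 2.0


class SampleKind(str, Enum):
    spiked = "spiked"
    matrix_matched_std = "matrix_matched_std"
    solvent_std = "solvent_std"
    blank = "blank"


class MeasurementRecord(BaseModel):
    """One peak area: analyte x matrix x kind x level x day x replicate x
    transition."""

    model_config = ConfigDict(frozen=True)

    analyte: str
    matrix: str
    sample_kind: SampleKind
    level: float
    day: int
    replicate: int
    transition_rank: str
    area: float

    @model_validator(mode="after")
    def _check(self) -> "MeasurementRecord":
        if self.sample_kind is SampleKind.blank and self.level != 0:
            raise ValueError("blank records must have level 0")
        if not math.isfinite(self.area) or self.area < 0:
            raise ValueError("area must be finite and >= 0")
        return self


class ValidationDesign(BaseModel):
    """Experimental plan: spike ladder, days, replicates, calibration."""

    model_config = ConfigDict(frozen=True)

    levels: tuple[float, ...]
    days: int = 3
    replicates_per_day: int = 4
    calibration_levels: tuple[float, ...] = CALIBRATION_LEVELS
    calibration_injections: int = 3
    include_blank: bool = True

    @model_validator(mode="after")
    def _check(self) -> "ValidationDesign":
        if self.days < 2:
            raise ValueError("days must be >= 2")
        if self.replicates_per_day < 2:
            raise ValueError("replicates_per_day must be >= 2")
        if list(self.levels) != sorted(set(self.levels)) or any(
            l <= 0 for l in self.levels
        ):
            raise ValueError("levels must be strictly increasing and positive")
        return self

    @classmethod
    def muscle(cls, **overrides) -> "ValidationDesign":
        return cls(levels=MUSCLE_LEVELS, **overrides)

    @classmethod
    def milk(cls, half_mrl_point: bool = False, **overrides) -> "ValidationDesign":
        levels = ((HALF_MRL_MILK_LEVEL,) if half_mrl_point else ()) + MILK_LEVELS
        return cls(levels=levels, **overrides)


class SimulationConfig(BaseModel):
    """Ground truths for one analyte x matrix simulation.

    CVs are percentages; ``matrix_effect_true`` uses the signed deviation
    convention (0 = no effect); ``recovery_true`` is a fraction.
    """

    model_config = ConfigDict(frozen=True)

    analyte: str
    matrix: str = "muscle"
    solvent_slope: float = 1000.0
    intercept: float = 0.0
    matrix_effect_true: float = 0.0
    recovery_true: float = 0.9
    cv_r_true: float = 6.0
    cv_wr_true: float = 9.0
    injection_cv: float = 2.0
    blank_noise_sd: float = 20.0
    ion_ratio_reference: float = 0.5
    ion_ratio_cv: float = 3.0
    seed: int = 0

    @field_validator("solvent_slope")
    @classmethod
    def _slope_positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("solvent_slope must be > 0")
        return v

    @field_validator("recovery_true")
    @classmethod
    def _recovery(cls, v: float) -> float:
        if not 0 < v <= 1.5:
            raise ValueError("recovery_true must be in (0, 1.5]")
        return v

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.cv_wr_true < self.cv_r_true:
            raise ConfigError(
                f"cv_wr_true ({self.cv_wr_true}) must be >= cv_r_true "
                f"({self.cv_r_true})"
            )
        if self.matrix_effect_true <= -100:
            raise ConfigError("matrix_effect_true must be > -100")
        return self

    @property
    def matrix_matched_slope(self) -> float:
        return self.solvent_slope * (1.0 + self.matrix_effect_true / 100.0)

    @property
    def sigma_r(self) -> float:
        return self.cv_r_true / 100.0

    @property
    def sigma_day(self) -> float:
        return math.sqrt((self.cv_wr_true / 100.0) ** 2 - self.sigma_r**2)


def generate_validation_dataset(
    cfg: SimulationConfig, design: ValidationDesign
) -> pd.DataFrame:
    """Simulate the full validation experiment for one analyte.

    Returns a tidy frame with ``MEASUREMENT_COLUMNS``: spiked replicates at
    every design level, per-day matrix-matched calibration standards, one
    solvent calibration series (day 0), and per-day blanks. Quantifier and
    qualifier rows are generated for spiked samples and blanks; calibration
    standards carry the quantifier transition (the one used for fitting).
    """
    rng = np.random.default_rng(cfg.seed)
    b_mm = cfg.matrix_matched_slope
    rows: list[tuple] = []

    day_effects = rng.normal(0.0, cfg.sigma_day, size=design.days)

    def add(kind, level, day, rep, rank, area):
        rows.append(
            (cfg.analyte, cfg.matrix, kind, level, day, rep, rank, max(0.0, area))
        )

    # spiked samples: full extraction, so recovery + day + replicate effects
    for di in range(design.days):
        day = di + 1
        for level in design.levels:
            expect = cfg.recovery_true * (cfg.intercept + b_mm * level)
            noise = rng.normal(0.0, cfg.sigma_r, size=design.replicates_per_day)
            for rep in range(1, design.replicates_per_day + 1):
                quant = expect * (1.0 + day_effects[di] + noise[rep - 1])
                add("spiked", level, day, rep, "quantifier", quant)
                qual = (
                    quant
                    * cfg.ion_ratio_reference
                    * (1.0 + rng.normal(0.0, cfg.ion_ratio_cv / 100.0))
                )
                add("spiked", level, day, rep, "qualifier", qual)
        # per-day blanks (one per replicate slot)
        for rep in range(1, design.replicates_per_day + 1):
            add("blank", 0.0, day, rep, "quantifier", rng.normal(0.0, cfg.blank_noise_sd))
            add("blank", 0.0, day, rep, "qualifier", rng.normal(0.0, cfg.blank_noise_sd))

    # matrix-matched standards: injection noise only, fitted per day
    cal_levels = ((0.0,) if design.include_blank else ()) + design.calibration_levels
    for di in range(design.days):
        day = di + 1
        for level in cal_levels:
            for inj in range(1, design.calibration_injections + 1):
                if level == 0.0:
                    area = rng.normal(0.0, cfg.blank_noise_sd)
                else:
                    expect = cfg.intercept + b_mm * level
                    area = expect * (1.0 + rng.normal(0.0, cfg.injection_cv / 100.0))
                add("matrix_matched_std", level, day, inj, "quantifier", area)

    # one solvent-standard curve (no matrix): day index 0
    for level in cal_levels:
        for inj in range(1, design.calibration_injections + 1):
            if level == 0.0:
                area = rng.normal(0.0, cfg.blank_noise_sd)
            else:
                expect = cfg.intercept + cfg.solvent_slope * level
                area = expect * (1.0 + rng.normal(0.0, cfg.injection_cv / 100.0))
            add("solvent_std", level, 0, inj, "quantifier", area)

    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def records_from_frame(frame: pd.DataFrame) -> list[MeasurementRecord]:
    """Validate a tidy measurement frame into typed records."""
    return [
        MeasurementRecord(**{k: row[k] for k in MEASUREMENT_COLUMNS})
        for _, row in frame.iterrows()
    ]


def simulate_internal_standard_areas(
    is_names: Sequence[str],
    seed: int = 0,
    mean_area: float = 5.0e5,
    cv_percent: float = 10.0,
) -> pd.DataFrame:
    """Quantifier areas for the internal standards spiked into every sample.

    The generator guarantees IS presence by construction (the spike is part
    of the protocol); areas scatter around ``mean_area`` with the given CV.
    """
    rng = np.random.default_rng(seed)
    areas = mean_area * (
        1.0 + rng.normal(0.0, cv_percent / 100.0, size=len(is_names))
    )
    return pd.DataFrame(
        {"analyte": list(is_names), "area": np.maximum(0.0, areas)}
    )


def spike_concentration(
    volume_ul: float, solution_conc_ug_ml: float, sample_mass_g: float
) -> float:
    """Concentration (ug/kg) added by spiking ``volume_ul`` of a solution at
    ``solution_conc_ug_ml`` into ``sample_mass_g`` of sample.

    ug added = volume_ul * 1e-3 mL * conc; kg of sample = mass_g * 1e-3, so
    the two 1e-3 factors cancel: c = volume * conc / mass.
    """
    if sample_mass_g <= 0:
        raise ValueError("sample mass must be > 0")
    if volume_ul < 0 or solution_conc_ug_ml < 0:
        raise ValueError("volume and concentration must be >= 0")
    return volume_ul * solution_conc_ug_ml / sample_mass_g
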