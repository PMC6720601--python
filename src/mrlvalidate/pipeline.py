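"""End-to-end validation pipeline: simulate/ingest -> calibrate -> report.

``run_pipeline`` drives the full analysis for a set of analyte scenarios in
one matrix: generate (or load) peak-area data, fit and prune per-day
matrix-matched calibrations, estimate the matrix effect against solvent
standards, estimate recovery, back-calculate recovery-corrected
concentrations against each day's own curve, run the per-level ANOVA,
pool the CVs, assign operative LOD/LOQ and CCalpha/CCbeta, screen the
acquisition table for cross-talk, and emit a per-analyte summary table.

Every threshold surfaces in the YAML config — nothing is hidden — and the
whole run is deterministic given the master seed (per-analyte generator
seeds are spawned from it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import datasets
from .calibration import (
    CalibrationFit,
    MatrixEffectResult,
    fit_calibration,
    matrix_effect,
    prune_working_range,
)
from .errors import ConfigError, InsufficientDataError, MissingLevelError
from .identification import is_qc_gate
from .method_table import MethodTable, parse_method_table, screen_interferences
from .precision import (
    LevelStats,
    LimitResult,
    anova_precision,
    assign_limits,
    detection_flags,
    detection_threshold,
    estimate_recovery,
    pool_cv,
)
from .synthetic import (
    SimulationConfig,
    ValidationDesign,
    generate_validation_dataset,
    simulate_internal_standard_areas,
)

log = logging.getLogger("mrlvalidate")


class Thresholds(BaseModel):
    """All decision thresholds used downstream, in one visible place."""

    model_config = ConfigDict(frozen=True)

    max_deviation: float = 20.0  # calibration back-calculation band, %
    cv_threshold: float = 20.0  # LOQ / fitness precision bound, %
    me_threshold: float = 20.0  # |ME| significance bound, %
    rt_window: float = 0.3  # co-elution window for cross-talk, min
    mz_tol: float = 0.5  # nominal-mass collision tolerance, m/z
    rrt_limit: float = 2.5  # relative retention time bound, %


class Scenario(BaseModel):
    """Ground truths for one analyte in the configured matrix."""

    model_config = ConfigDict(frozen=True)

    analyte: str
    recovery_true: float = 0.9
    cv_r_true: float = 6.0
    cv_wr_true: float = 9.0
    matrix_effect_true: float = 0.0
    solvent_slope: float = 1000.0
    intercept: float = 0.0
    injection_cv: float = 2.0
    blank_noise_sd: float = 20.0
    ion_ratio_reference: float = 0.5
    mrl: float | None = None


class PipelineConfig(BaseModel):
    """YAML-loadable configuration of a full validation run."""

    model_config = ConfigDict(frozen=True)

    matrix: str = "muscle"
    seed: int = 0
    method_table: str | None = None  # None -> bundled acquisition table
    areas_csv: str | None = None  # analyze measured data instead of simulating
    scenarios: tuple[Scenario, ...] = ()
    days: int = 3
    replicates_per_day: int = 4
    levels: tuple[float, ...] | None = None  # None -> matrix default ladder
    calibration_injections: int = 3
    thresholds: Thresholds = Field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.model_validate(raw)

    def design(self) -> ValidationDesign:
        common = dict(
            days=self.days,
            replicates_per_day=self.replicates_per_day,
            calibration_injections=self.calibration_injections,
        )
        if self.levels is not None:
            return ValidationDesign(levels=self.levels, **common)
        if self.matrix == "milk":
            return ValidationDesign.milk(**common)
        return ValidationDesign.muscle(**common)


def spawn_seed(master: int, index: int) -> int:
    """Deterministic per-scenario child seed below 2**31."""
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class AnalyteSummary:
    """One row of the validation report."""

    analyte: str
    matrix: str
    slope: float
    intercept: float
    r_squared: float
    working_range: tuple[float, float]
    removed_levels: tuple[float, ...]
    nonlinear: bool
    me: MatrixEffectResult | None
    recovery: float
    per_level: tuple[LevelStats, ...]
    cv_r_pooled: float
    cv_wr_pooled: float
    limits: LimitResult
    interference_with: tuple[str, ...] = ()


def analyze_validation_frame(
    frame: pd.DataFrame,
    analyte: str,
    matrix: str,
    thresholds: Thresholds = Thresholds(),
    mrl: float | None = None,
) -> AnalyteSummary:
    """Run the full per-analyte statistics on a tidy measurement frame."""
    sub = frame[(frame["analyte"] == analyte) & (frame["matrix"] == matrix)]
    if sub.empty:
        raise InsufficientDataError(f"no records for {analyte!r} in {matrix!r}")
    quant = sub[sub["transition_rank"] == "quantifier"]
    mm = quant[quant["sample_kind"] == "matrix_matched_std"]
    solvent = quant[quant["sample_kind"] == "solvent_std"]
    spiked = quant[quant["sample_kind"] == "spiked"]
    blanks = sub[sub["sample_kind"] == "blank"]

    # pooled matrix-matched calibration (all days), pruned to working range
    pooled_fit = prune_working_range(
        fit_calibration(mm[["level", "area"]]), thresholds.max_deviation
    )

    me = None
    if not solvent.empty:
        solvent_fit = fit_calibration(solvent[["level", "area"]])
        me = matrix_effect(pooled_fit, solvent_fit, thresholds.me_threshold)

    recovery = estimate_recovery(spiked, mm)
    rec_fraction = recovery.overall_recovery / 100.0

    # per-day curves: back-calculate each day's spiked areas on its own line
    day_fits: dict[int, CalibrationFit] = {}
    for day, g in mm.groupby("day"):
        day_fits[int(day)] = prune_working_range(
            fit_calibration(g[["level", "area"]]), thresholds.max_deviation
        )
    conc_frames = []
    for day, g in spiked.groupby("day"):
        fit = day_fits.get(int(day), pooled_fit)
        conc = fit.back_calculate(g["area"].to_numpy()) / rec_fraction
        conc_frames.append(
            pd.DataFrame({"level": g["level"], "day": day, "conc": conc})
        )
    conc_df = pd.concat(conc_frames, ignore_index=True)

    if blanks.empty:
        threshold = 0.0
    else:
        threshold = detection_threshold(blanks["area"])
    detect = detection_flags(sub, threshold)

    rec_by_level = dict(recovery.per_level_recovery)
    level_stats: list[LevelStats] = []
    for level, g in conc_df.groupby("level"):
        res = anova_precision(g[["day", "conc"]])
        level_stats.append(
            LevelStats(
                level=float(level),
                cv_r=res.cv_r,
                cv_wr=res.cv_wr,
                detectable=detect.get(float(level), True),
                n=res.n_total,
                recovery=rec_by_level.get(float(level)),
                mean_conc=res.grand_mean,
            )
        )
    level_stats.sort(key=lambda s: s.level)
    cv_r_pooled = pool_cv([(s.cv_r, s.n) for s in level_stats])
    cv_wr_pooled = pool_cv([(s.cv_wr, s.n) for s in level_stats])
    limits = assign_limits(
        level_stats, cv_wr_pooled, mrl=mrl, cv_threshold=thresholds.cv_threshold
    )
    return AnalyteSummary(
        analyte=analyte,
        matrix=matrix,
        slope=pooled_fit.slope,
        intercept=pooled_fit.intercept,
        r_squared=pooled_fit.r_squared,
        working_range=pooled_fit.working_range,
        removed_levels=pooled_fit.removed_levels,
        nonlinear=pooled_fit.nonlinear,
        me=me,
        recovery=recovery.overall_recovery,
        per_level=tuple(level_stats),
        cv_r_pooled=cv_r_pooled,
        cv_wr_pooled=cv_wr_pooled,
        limits=limits,
    )


@dataclass(frozen=True)
class ValidationReport:
    """Pipeline output: one summary per analyte plus run-level findings."""

    matrix: str
    seed: int
    rows: tuple[AnalyteSummary, ...]
    interference_pairs: tuple[tuple[str, str], ...]
    excluded: tuple[tuple[str, str], ...]  # (analyte, reason)
    releasable: bool
    config: PipelineConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        out = []
        for r in self.rows:
            out.append(
                {
                    "analyte": r.analyte,
                    "matrix": r.matrix,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "r_squared": r.r_squared,
                    "range_low": r.working_range[0],
                    "range_high": r.working_range[1],
                    "removed_levels": ";".join(str(l) for l in r.removed_levels),
                    "nonlinear": r.nonlinear,
                    "me_percent": r.me.me_percent if r.me else float("nan"),
                    "me_significant": r.me.significant if r.me else False,
                    "recovery": r.recovery,
                    "cv_r_pooled": r.cv_r_pooled,
                    "cv_wr_pooled": r.cv_wr_pooled,
                    "lod": r.limits.lod,
                    "loq": r.limits.loq,
                    "mrl": r.limits.mrl,
                    "cc_alpha": r.limits.cc_alpha,
                    "cc_beta": r.limits.cc_beta,
                    "fitness": r.limits.fitness.value,
                    "interference_with": ";".join(r.interference_with),
                }
            )
        return pd.DataFrame(out)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    def write_markdown(self, path) -> None:
        df = self.to_frame()
        lines = [
            f"# Validation report — {self.matrix} (seed {self.seed})",
            "",
            f"Releasable: {'yes' if self.releasable else 'NO — IS gate failed'}",
            "",
        ]
        if self.interference_pairs:
            lines.append("Cross-talk warnings:")
            for a, b in self.interference_pairs:
                lines.append(f"- {a} / {b}: precursor collision with co-elution")
            lines.append("")
        if self.excluded:
            lines.append("Excluded analytes:")
            for a, reason in self.excluded:
                lines.append(f"- {a}: {reason}")
            lines.append("")
        cols = [
            "analyte", "recovery", "cv_r_pooled", "cv_wr_pooled", "me_percent",
            "lod", "loq", "cc_alpha", "cc_beta", "fitness",
        ]
        sub = df[cols].round(2)
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * len(cols))
        for _, row in sub.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row.tolist()) + " |")
        Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(config) -> ValidationReport:
    """Execute the full pipeline from a config object or YAML path."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    if config.areas_csv is None and not config.scenarios:
        raise ConfigError("config needs either scenarios or an areas_csv")

    if config.method_table is None:
        table = datasets.load_method_table()
    else:
        table = parse_method_table(config.method_table)
    log.info("method table: %d transitions, %d targets", len(table),
             len(table.target_analytes))

    pairs = screen_interferences(
        table, rt_window=config.thresholds.rt_window, mz_tol=config.thresholds.mz_tol
    )
    pair_names = tuple((p.analyte_a, p.analyte_b) for p in pairs)

    allowed = set(table.analytes_in(config.matrix))
    design = config.design()

    frames: list[pd.DataFrame] = []
    excluded: list[tuple[str, str]] = []
    mrls: dict[str, float | None] = {}
    if config.areas_csv is not None:
        frames.append(pd.read_csv(config.areas_csv))
        for sc in config.scenarios:
            mrls[sc.analyte] = sc.mrl
    else:
        for i, sc in enumerate(config.scenarios):
            if sc.analyte in table.target_analytes and sc.analyte not in allowed:
                excluded.append(
                    (sc.analyte, f"not acquired in matrix {config.matrix!r}")
                )
                log.info("excluding %s: not acquired in %s", sc.analyte, config.matrix)
                continue
            sim = SimulationConfig(
                analyte=sc.analyte,
                matrix=config.matrix,
                solvent_slope=sc.solvent_slope,
                intercept=sc.intercept,
                matrix_effect_true=sc.matrix_effect_true,
                recovery_true=sc.recovery_true,
                cv_r_true=sc.cv_r_true,
                cv_wr_true=sc.cv_wr_true,
                injection_cv=sc.injection_cv,
                blank_noise_sd=sc.blank_noise_sd,
                ion_ratio_reference=sc.ion_ratio_reference,
                seed=spawn_seed(config.seed, i),
            )
            frames.append(generate_validation_dataset(sim, design))
            mrls[sc.analyte] = sc.mrl
    frame = pd.concat(frames, ignore_index=True)
    log.info("measurement records: %d", len(frame))

    # internal-standard gate on a simulated routine sample
    is_names = table.internal_standards
    is_areas = simulate_internal_standard_areas(
        is_names, seed=spawn_seed(config.seed, 10_000)
    )
    gate = is_qc_gate(
        dict(zip(is_areas["analyte"], is_areas["area"])),
        threshold=100.0,
        expected=is_names,
    )

    interference_lookup: dict[str, list[str]] = {}
    for a, b in pair_names:
        interference_lookup.setdefault(a, []).append(b)
        interference_lookup.setdefault(b, []).append(a)

    rows = []
    for analyte in sorted(frame["analyte"].unique()):
        summary = analyze_validation_frame(
            frame,
            analyte,
            config.matrix,
            thresholds=config.thresholds,
            mrl=mrls.get(analyte),
        )
        if mrls.get(analyte) is None:
            log.warning("no MRL for %s: CCalpha/CCbeta omitted", analyte)
        rows.append(
            AnalyteSummary(
                **{
                    **summary.__dict__,
                    "interference_with": tuple(interference_lookup.get(analyte, ())),
                }
            )
        )
    return ValidationReport(
        matrix=config.matrix,
        seed=config.seed,
        rows=tuple(rows),
        interference_pairs=pair_names,
        excluded=tuple(excluded),
        releasable=gate.passed,
        config=config,
    )
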