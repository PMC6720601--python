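"""Recovery, ANOVA precision, pooled CVs, CCalpha/CCbeta and LOD/LOQ.

The quantities estimated here are the core performance characteristics of a
quantitative residue method:

* **Recovery** — per spike level, the ratio of the mean spiked-sample peak
  area to the mean matrix-matched-standard area at the same concentration
  (x100). Matrix-matched standards skip the extraction, so the ratio
  isolates the preparation loss; routine results are divided by it.
* **Precision** — a one-way random-effects ANOVA with *day* as the grouping
  factor decomposes the variance of recovery-corrected back-calculated
  concentrations at each level into a within-day (repeatability) component
  s2_r = MS_within and a between-day component
  s2_L = max(0, (MS_between - MS_within)/n0); their sum is the within-lab
  reproducibility variance s2_wR. CVs are 100*s/grand-mean. Per-level CVs
  are pooled across the ladder with degrees-of-freedom weights:

      CV_pooled = sqrt( sum (n_i - 1) CV_i^2 / sum (n_i - 1) )

* **Decision limits** — with the pooled within-lab CV (as a fraction) and a
  one-sided 5% factor of 1.64:

      CCalpha = MRL * (1 + 1.64 CV),   CCbeta = CCalpha * (1 + 1.64 CV)

  so CCbeta/CCalpha = CCalpha/MRL exactly.
* **Operative LOD/LOQ** — rather than a signal-to-noise extrapolation, the
  LOD is the lowest validated level at which the analyte is detected (both
  transitions above the blank-based threshold in every replicate) and the
  LOQ the lowest level where both CV_r and CV_wR stay at or below a
  precision threshold (default 20%). A method whose pooled CV exceeds the
  threshold, or with no quantifiable level, is fit for screening only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MissingLevelError, NotDetectableError

CV_THRESHOLD_DEFAULT = 20.0
ONE_SIDED_95 = 1.64


@dataclass(frozen=True)
class AccuracyResult:
    """Per-level and overall recovery (percent)."""

    per_level_recovery: tuple[tuple[float, float], ...]
    overall_recovery: float

    def recovery_at(self, level: float) -> float:
        for lv, rec in self.per_level_recovery:
            if lv == level:
                return rec
        raise KeyError(level)


def estimate_recovery(
    spiked: pd.DataFrame,
    standards: pd.DataFrame,
    levels: Sequence[float] | None = None,
) -> AccuracyResult:
    """Recovery from spiked samples vs matrix-matched standards.

    Per level: mean(spiked areas) / mean(standard areas) x 100; overall is
    the unweighted mean across levels. With ``levels=None`` the levels
    shared by both inputs are used; an explicitly requested level absent
    from the standards raises ``MissingLevelError`` naming it.
    """
    sp = spiked[spiked["level"] > 0] if "level" in spiked else spiked
    spiked_means = sp.groupby("level")["area"].mean()
    std = standards[standards["level"] > 0]
    std_means = std.groupby("level")["area"].mean()
    if levels is None:
        use = sorted(set(spiked_means.index) & set(std_means.index))
        if not use:
            raise MissingLevelError("no level present in both spiked and standards")
    else:
        missing = [lv for lv in levels if lv not in std_means.index]
        if missing:
            raise MissingLevelError(f"levels missing from standards: {missing}")
        missing_sp = [lv for lv in levels if lv not in spiked_means.index]
        if missing_sp:
            raise MissingLevelError(f"levels missing from spiked: {missing_sp}")
        use = list(levels)
    per_level = tuple(
        (float(lv), float(spiked_means[lv] / std_means[lv] * 100.0)) for lv in use
    )
    overall = float(np.mean([rec for _, rec in per_level]))
    return AccuracyResult(per_level_recovery=per_level, overall_recovery=overall)


@dataclass(frozen=True)
class AnovaResult:
    """One-way random-effects components at a single level."""

    cv_r: float
    cv_wr: float
    grand_mean: float
    s2_within: float
    s2_between: float
    ms_within: float
    ms_between: float
    n_total: int

    def __iter__(self):
        # allows ``cv_r, cv_wr = anova_precision(...)``
        return iter((self.cv_r, self.cv_wr))


def anova_precision(values, days=None) -> AnovaResult:
    """Repeatability and within-lab reproducibility CVs at one level.

    ``values`` is either a tidy frame with ``day`` and ``conc`` columns or a
    sequence of per-day sequences. Run on recovery-corrected back-calculated
    concentrations. Requires >= 2 days with >= 2 replicates each.

    The between-day variance uses the unbalanced-design coefficient
    n0 = (N - sum n_i^2 / N) / (a - 1), which reduces to the common
    replicate count for balanced designs; a negative component estimate is
    truncated at zero.
    """
    if isinstance(values, pd.DataFrame):
        groups = [g["conc"].to_numpy(float) for _, g in values.groupby("day")]
    elif days is not None:
        df = pd.DataFrame({"day": list(days), "conc": list(values)})
        return anova_precision(df)
    else:
        groups = [np.asarray(g, dtype=float) for g in values]
    a = len(groups)
    if a < 2:
        raise InsufficientDataError("need >= 2 days")
    if any(len(g) < 2 for g in groups):
        raise InsufficientDataError("every day needs >= 2 replicates")
    n_i = np.array([len(g) for g in groups])
    n_total = int(n_i.sum())
    grand = float(np.concatenate(groups).mean())
    if grand == 0:
        raise NotDetectableError("zero grand mean: CV undefined")
    means = np.array([g.mean() for g in groups])
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_within = ss_within / (n_total - a)
    ss_between = float((n_i * (means - grand) ** 2).sum())
    ms_between = ss_between / (a - 1)
    n0 = (n_total - float((n_i**2).sum()) / n_total) / (a - 1)
    s2_r = ms_within
    s2_l = max(0.0, (ms_between - ms_within) / n0)
    s2_wr = s2_r + s2_l
    return AnovaResult(
        cv_r=100.0 * math.sqrt(s2_r) / abs(grand),
        cv_wr=100.0 * math.sqrt(s2_wr) / abs(grand),
        grand_mean=grand,
        s2_within=s2_r,
        s2_between=s2_l,
        ms_within=ms_within,
        ms_between=ms_between,
        n_total=n_total,
    )


def pool_cv(per_level: Iterable[tuple[float, int]]) -> float:
    """Degrees-of-freedom-weighted RMS of per-level CVs.

    ``per_level`` is an iterable of (CV%, n_replicates); the pooled value is
    sqrt( sum (n_i-1) CV_i^2 / sum (n_i-1) ).
    """
    items = list(per_level)
    if not items:
        raise InsufficientDataError("pool_cv needs at least one level")
    if any(n < 2 for _, n in items):
        raise InsufficientDataError("every level needs n >= 2")
    num = sum((n - 1) * cv**2 for cv, n in items)
    den = sum(n - 1 for _, n in items)
    return math.sqrt(num / den)


def cc_limits(mrl: float, cv_wr_pooled: float) -> tuple[float, float]:
    """Decision limit CCalpha and detection capability CCbeta at an MRL.

    ``cv_wr_pooled`` is in percent and converted to a fraction; both limits
    apply the same one-sided 95% factor, so CCbeta/CCalpha = CCalpha/MRL.
    """
    if mrl <= 0:
        raise ValueError("mrl must be > 0")
    if cv_wr_pooled < 0:
        raise ValueError("cv must be >= 0")
    cv = cv_wr_pooled / 100.0
    cc_alpha = mrl * (1.0 + ONE_SIDED_95 * cv)
    cc_beta = cc_alpha * (1.0 + ONE_SIDED_95 * cv)
    return cc_alpha, cc_beta


class Fitness(str, Enum):
    confirmation = "confirmation"
    screening_only = "screening_only"


@dataclass(frozen=True)
class LevelStats:
    """Accuracy/precision summary of one validation level."""

    level: float
    cv_r: float
    cv_wr: float
    detectable: bool
    n: int
    recovery: float | None = None
    mean_conc: float | None = None


@dataclass(frozen=True)
class PrecisionResult:
    """Per-level CVs plus the pooled indices."""

    per_level: tuple[LevelStats, ...]
    cv_r_pooled: float
    cv_wr_pooled: float


@dataclass(frozen=True)
class LimitResult:
    """Operative limits and fitness class of an analyte/matrix pairing."""

    lod: float | None
    loq: float | None
    fitness: Fitness
    mrl: float | None = None
    cc_alpha: float | None = None
    cc_beta: float | None = None


def detection_threshold(blank_areas) -> float:
    """Blank-based surrogate for an S/N > 3 rule: mean + 3 SD of blanks."""
    arr = np.asarray(list(blank_areas), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no blank areas")
    return float(arr.mean() + 3.0 * arr.std(ddof=1 if arr.size > 1 else 0))


def detection_flags(
    frame: pd.DataFrame, threshold: float
) -> dict[float, bool]:
    """Per-level detectability: every replicate of both transitions above
    the blank threshold."""
    sp = frame[(frame["sample_kind"] == "spiked") & (frame["level"] > 0)]
    return {
        float(level): bool((g["area"] > threshold).all())
        for level, g in sp.groupby("level")
    }


def assign_limits(
    per_level: Sequence[LevelStats],
    cv_wr_pooled: float,
    mrl: float | None = None,
    cv_threshold: float = CV_THRESHOLD_DEFAULT,
) -> LimitResult:
    """Operative LOD/LOQ, fitness class, and (with an MRL) CCalpha/CCbeta.

    LOD = lowest level detectable; LOQ = lowest level with both CV_r and
    CV_wR <= ``cv_threshold``. Fitness is ``screening_only`` when no level
    qualifies for the LOQ or the pooled within-lab CV exceeds the threshold.
    """
    stats = sorted(per_level, key=lambda s: s.level)
    if not stats:
        raise InsufficientDataError("no level statistics supplied")
    lod = next((s.level for s in stats if s.detectable), None)
    loq = next(
        (
            s.level
            for s in stats
            if s.detectable and s.cv_r <= cv_threshold and s.cv_wr <= cv_threshold
        ),
        None,
    )
    fitness = (
        Fitness.screening_only
        if loq is None or cv_wr_pooled > cv_threshold
        else Fitness.confirmation
    )
    cc_a = cc_b = None
    if mrl is not None:
        cc_a, cc_b = cc_limits(mrl, cv_wr_pooled)
    return LimitResult(
        lod=lod, loq=loq, fitness=fitness, mrl=mrl, cc_alpha=cc_a, cc_beta=cc_b
    )
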