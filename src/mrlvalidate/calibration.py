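"""Matrix-matched / solvent calibration: linearity and matrix effect.

Calibration curves are unweighted ordinary least squares fits of mean peak
area (injections averaged per level) against concentration, with the blank
included as a genuine level-0 point and a free intercept. Linearity is
judged per point through the back-calculated concentration

    C_measured = (mean area - a) / b,      deviation% = (C_meas - C_true)/C_true * 100

and a point ladder is pruned from the bottom until every remaining non-zero
level back-calculates within a configured band (default +/-20%), mirroring
how low calibration points with scarce response are discarded in practice.

The matrix effect compares matrix-matched and solvent slopes. The raw slope
ratio b_MM/b_S x 100 is exposed, but the headline number uses the signed
deviation convention (ratio - 1) x 100, so suppression is negative and
enhancement positive; |ME| above a threshold (default 20%) is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

MAX_DEVIATION_DEFAULT = 20.0
ME_THRESHOLD_DEFAULT = 20.0


@dataclass(frozen=True)
class CalibrationFit:
    """An OLS calibration line plus its linearity diagnostics."""

    slope: float
    intercept: float
    points: tuple[tuple[float, float, int], ...]  # (level, mean_area, n_injections)
    deviations: dict[float, float]  # level > 0 -> back-calculated deviation %
    retained_levels: tuple[float, ...]
    removed_levels: tuple[float, ...] = ()
    r_squared: float = float("nan")
    nonlinear: bool = False

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.points)

    def back_calculate(self, area) -> float | np.ndarray:
        """Concentration(s) corresponding to ``area`` on this line."""
        return (np.asarray(area, dtype=float) - self.intercept) / self.slope

    @property
    def working_range(self) -> tuple[float, float]:
        nonzero = [l for l in self.retained_levels if l > 0]
        return (min(nonzero), max(nonzero))


def _mean_points(records) -> list[tuple[float, float, int]]:
    """Average injections per level from a tidy frame or (level, area) pairs."""
    if isinstance(records, pd.DataFrame):
        grouped = records.groupby("level")["area"]
        return [
            (float(level), float(areas.mean()), int(areas.size))
            for level, areas in grouped
        ]
    df = pd.DataFrame(list(records), columns=["level", "area"])
    return _mean_points(df)


def fit_calibration(records, include_blank: bool = True) -> CalibrationFit:
    """Unweighted OLS of mean area vs level.

    ``records`` is a tidy frame with ``level``/``area`` columns (one sample
    kind only) or an iterable of (level, area) pairs; injections are
    averaged per level before fitting. The blank enters as a level-0 point
    unless ``include_blank`` is false. Requires >= 3 distinct levels.
    """
    points = _mean_points(records)
    if not include_blank:
        points = [p for p in points if p[0] > 0]
    points.sort()
    if len(points) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct levels to fit, got {len(points)}"
        )
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    if np.ptp(x) == 0:
        raise InsufficientDataError("zero variance in levels: singular design")
    # closed-form simple OLS
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = float(ybar - slope * xbar)
    ss_res = float(((y - (intercept + slope * x)) ** 2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    deviations = {}
    for level, mean_area, _ in points:
        if level > 0:
            c_meas = (mean_area - intercept) / slope
            deviations[level] = (c_meas - level) / level * 100.0
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        points=tuple(points),
        deviations=deviations,
        retained_levels=tuple(p[0] for p in points),
        r_squared=r2,
    )


def prune_working_range(
    fit: CalibrationFit, max_dev: float = MAX_DEVIATION_DEFAULT
) -> CalibrationFit:
    """Drop low levels until every back-calculated deviation is within band.

    While any non-zero point exceeds |``max_dev``| %, the lowest remaining
    non-zero level is removed and the line refitted; stops when all points
    comply or only three non-zero levels remain. A ladder that still fails
    at three levels is flagged ``nonlinear``.
    """
    if max_dev <= 0:
        raise ValueError("max_dev must be > 0")
    current = fit
    removed: list[float] = list(fit.removed_levels)
    while True:
        offending = [l for l, d in current.deviations.items() if abs(d) > max_dev]
        if not offending:
            return replace(current, removed_levels=tuple(removed))
        nonzero = [l for l in current.levels if l > 0]
        if len(nonzero) <= 3:
            return replace(current, removed_levels=tuple(removed), nonlinear=True)
        drop = min(nonzero)
        removed.append(drop)
        kept = [(l, a) for l, a, _ in current.points if l != drop]
        refit = fit_calibration(kept)
        # carry per-level injection counts through the refit
        counts = {l: n for l, _, n in current.points if l != drop}
        refit = replace(
            refit,
            points=tuple((l, a, counts[l]) for l, a, _ in refit.points),
        )
        current = refit


@dataclass(frozen=True)
class MatrixEffectResult:
    """Slope-ratio matrix effect, signed deviation convention."""

    me_percent: float
    ratio_percent: float  # raw b_MM/b_S x 100
    b_mm: float
    b_s: float
    significant: bool
    threshold: float = ME_THRESHOLD_DEFAULT


def matrix_effect(
    fit_mm: CalibrationFit,
    fit_s: CalibrationFit,
    threshold: float = ME_THRESHOLD_DEFAULT,
) -> MatrixEffectResult:
    """Matrix effect from matrix-matched vs solvent calibration slopes.

    ``me_percent = (b_MM/b_S - 1) * 100`` — negative for ionization
    suppression, positive for enhancement; significant when |ME| exceeds
    ``threshold``. The raw percentage ratio is reported alongside.
    """
    if fit_s.slope == 0:
        raise ZeroDivisionError("solvent slope is zero; matrix effect undefined")
    if fit_mm.slope <= 0 or fit_s.slope <= 0:
        raise ValueError("slopes must be > 0")
    ratio = fit_mm.slope / fit_s.slope
    me = (ratio - 1.0) * 100.0
    return MatrixEffectResult(
        me_percent=me,
        ratio_percent=ratio * 100.0,
        b_mm=fit_mm.slope,
        b_s=fit_s.slope,
        significant=abs(me) > threshold,
        threshold=threshold,
    )
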