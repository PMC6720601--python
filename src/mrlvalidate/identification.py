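"""Identity confirmation: ion ratio, relative retention time, IS gate.

A residue finding is only *confirmed* when three independent checks agree:

* the qualifier/quantifier peak-area ratio matches the reference ratio of
  same-batch matrix-matched standards within a tolerance band that widens
  as the qualifier gets weaker (>50% of the quantifier: +/-20%; >20-50%:
  +/-25%; >10-20%: +/-30%; <=10%: +/-50% — the regulatory relative-intensity
  table for LC-MS/MS);
* the retention time relative to an internal standard deviates from the
  reference RRT by less than a limit (default 2.5%);
* the internal-standard quality gate passes: every IS spiked into the
  sample (eight in the shipped method) is detected, proving the extraction
  and injection succeeded. No result is releasable otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import NotDetectableError

RRT_LIMIT_DEFAULT = 2.5

#: (lower-exclusive reference bound, tolerance %) — regulatory ion-ratio bands.
ION_RATIO_BANDS = ((0.50, 20.0), (0.20, 25.0), (0.10, 30.0), (0.0, 50.0))


def ion_ratio_band(reference: float) -> float:
    """Tolerance (+/- %) applicable to a reference ion ratio in (0, 1]."""
    if not 0 < reference <= 1:
        raise ValueError("reference ion ratio must be in (0, 1]")
    for lower, band in ION_RATIO_BANDS:
        if reference > lower:
            return band
    raise AssertionError("unreachable: bands cover (0, 1]")


@dataclass(frozen=True)
class IonRatioCheck:
    ratio: float
    reference: float
    band: float
    relative_deviation: float
    passed: bool


def ion_ratio_check(
    area_qual: float, area_quant: float, reference: float
) -> IonRatioCheck:
    """Compare the measured qualifier/quantifier ratio to its reference.

    Passes when the relative deviation |ratio - ref|/ref is within the band
    selected from the reference's relative intensity.
    """
    if area_quant <= 0:
        raise NotDetectableError("quantifier area is zero: analyte not detectable")
    if area_qual < 0:
        raise ValueError("qualifier area must be >= 0")
    band = ion_ratio_band(reference)
    ratio = area_qual / area_quant
    rel_dev = abs(ratio - reference) / reference * 100.0
    return IonRatioCheck(
        ratio=ratio,
        reference=reference,
        band=band,
        relative_deviation=rel_dev,
        passed=rel_dev <= band,
    )


@dataclass(frozen=True)
class RrtCheck:
    rrt: float
    reference: float
    deviation_percent: float
    passed: bool


def rrt_check(
    rt_analyte: float,
    rt_is: float,
    rrt_reference: float,
    limit: float = RRT_LIMIT_DEFAULT,
) -> RrtCheck:
    """Relative-retention-time agreement with the reference standard.

    deviation% = |rt_analyte/rt_is - RRT_ref| / RRT_ref x 100, passing when
    strictly below ``limit``.
    """
    if rt_is <= 0:
        raise ValueError("internal-standard retention time must be > 0")
    if rt_analyte <= 0 or rrt_reference <= 0:
        raise ValueError("retention times and reference RRT must be > 0")
    rrt = rt_analyte / rt_is
    deviation = abs(rrt - rrt_reference) / rrt_reference * 100.0
    return RrtCheck(
        rrt=rrt, reference=rrt_reference, deviation_percent=deviation,
        passed=deviation < limit,
    )


@dataclass(frozen=True)
class IsGateResult:
    passed: bool
    missing: tuple[str, ...]
    below_threshold: tuple[str, ...]


def is_qc_gate(
    is_areas: Mapping[str, float],
    threshold: float,
    expected: Sequence[str],
) -> IsGateResult:
    """Internal-standard gate: all expected ISs detected above threshold.

    ``is_areas`` maps IS name -> quantifier area in the sample; an absent or
    sub-threshold IS fails the gate and is named in the result.
    """
    missing = tuple(name for name in expected if name not in is_areas)
    below = tuple(
        name
        for name in expected
        if name in is_areas and is_areas[name] <= threshold
    )
    return IsGateResult(
        passed=not missing and not below, missing=missing, below_threshold=below
    )


@dataclass(frozen=True)
class IdentificationResult:
    """Conjunction of the three confirmation sub-checks for one analyte."""

    analyte: str
    ion_ratio: IonRatioCheck
    rrt: RrtCheck
    is_gate_pass: bool
    confirmed: bool


def confirm_identification(
    analyte: str,
    ion_ratio: IonRatioCheck,
    rrt: RrtCheck,
    gate: IsGateResult,
) -> IdentificationResult:
    return IdentificationResult(
        analyte=analyte,
        ion_ratio=ion_ratio,
        rrt=rrt,
        is_gate_pass=gate.passed,
        confirmed=ion_ratio.passed and rrt.passed and gate.passed,
    )
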