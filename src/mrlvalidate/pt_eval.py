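"""Proficiency-test evaluation against consensus values and ranges.

PT organizers assign each test material a consensus concentration and an
acceptability range; a laboratory result inside the range is satisfactory.
The organizers' standard deviation is not always published, so an advisory
z-score is reconstructed by reading the acceptability range as consensus
+/- 2 sigma, i.e. sigma = (high - low) / 4:

    z = (found - consensus) / sigma

The authoritative verdict stays the range check; |z| <= 2 coincides with it
up to the rounding of the printed bounds. A "not detected" result counts as
out-of-range whenever a consensus was assigned (the material did contain
the analyte) and carries no numeric z. Materials whose consensus was never
assigned are not evaluable and excluded from pass/fail counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

NOT_ASSIGNED_TOKENS = {"", "na", "n/a", "not assigned", "-", "nan"}
NOT_DETECTED_TOKENS = {"nd", "not detected", "<lod"}


class PTRecord(BaseModel):
    """One proficiency-test result for one analyte in one material."""

    model_config = ConfigDict(frozen=True)

    sample_code: str
    matrix: str
    analyte: str
    found: float | None  # None = not detected
    consensus: float | None  # None = not assigned
    range_low: float | None
    range_high: float | None

    @model_validator(mode="after")
    def _check(self) -> "PTRecord":
        if self.range_low is not None and self.range_high is not None:
            if self.range_low >= self.range_high:
                raise ValueError("acceptability range low must be < high")
            if self.consensus is not None and not (
                self.range_low < self.consensus < self.range_high
            ):
                raise ValueError("consensus must lie inside the range")
        return self


@dataclass(frozen=True)
class PTEvaluation:
    in_range: bool | None  # None = not evaluable
    z: float | None
    sigma: float | None


def _parse_quantity(token, not_detected_ok: bool = False) -> float | None:
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return None
    s = str(token).strip().lower()
    if s in NOT_ASSIGNED_TOKENS or (not_detected_ok and s in NOT_DETECTED_TOKENS):
        return None
    return float(token)


def evaluate_pt(record: PTRecord) -> PTEvaluation:
    """Score one PT record: range verdict plus advisory z."""
    if record.consensus is None or record.range_low is None or record.range_high is None:
        return PTEvaluation(in_range=None, z=None, sigma=None)
    sigma = (record.range_high - record.range_low) / 4.0
    if record.found is None:
        # material contained the analyte but the method missed it
        return PTEvaluation(in_range=False, z=None, sigma=sigma)
    in_range = record.range_low <= record.found <= record.range_high
    z = (record.found - record.consensus) / sigma
    return PTEvaluation(in_range=in_range, z=z, sigma=sigma)


def load_pt_records(
    path, method: Literal["qqq", "orbitrap"] = "qqq"
) -> list[PTRecord]:
    """Read a PT-record CSV, selecting one method's found concentrations.

    Expects columns sample_code, matrix, analyte, consensus, range_low,
    range_high and found_qqq/found_orbitrap (or a plain ``found`` column).
    """
    df = pd.read_csv(path, dtype=str)
    found_col = f"found_{method}" if f"found_{method}" in df.columns else "found"
    records = []
    for _, row in df.iterrows():
        records.append(
            PTRecord(
                sample_code=row["sample_code"].strip(),
                matrix=row["matrix"].strip(),
                analyte=row["analyte"].strip(),
                found=_parse_quantity(row[found_col], not_detected_ok=True),
                consensus=_parse_quantity(row.get("consensus")),
                range_low=_parse_quantity(row.get("range_low")),
                range_high=_parse_quantity(row.get("range_high")),
            )
        )
    return records


def pt_summary(records: list[PTRecord]) -> pd.DataFrame:
    """Evaluate every record into a tidy verdict table."""
    rows = []
    for rec in records:
        ev = evaluate_pt(rec)
        rows.append(
            {
                "sample_code": rec.sample_code,
                "matrix": rec.matrix,
                "analyte": rec.analyte,
                "found": rec.found,
                "consensus": rec.consensus,
                "range_low": rec.range_low,
                "range_high": rec.range_high,
                "in_range": ev.in_range,
                "z": ev.z,
            }
        )
    return pd.DataFrame(rows)
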