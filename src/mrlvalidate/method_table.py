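"""SRM acquisition-method model and cross-talk (interference) screening.

A multiclass residue method acquires two selected-reaction-monitoring (SRM)
transitions per target analyte on a unit-resolution triple quadrupole. Two
co-eluting analytes whose precursor ions share the same nominal m/z can
bleed into each other's transitions ("hidden" transitions), inflating peak
areas and producing false positives. This module holds the acquisition table
(analyte, retention time, adduct, precursor/product m/z, collision energy,
quantifier/qualifier rank) and screens every analyte pair for that failure
mode.
"""

from __future__ import annotations

import itertools
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import DuplicateTransitionError, SchemaError

REQUIRED_COLUMNS = (
    "analyte",
    "role",
    "matrices",
    "rt_min",
    "adduct",
    "precursor_mz",
    "product_mz",
    "ce_ev",
    "rank",
)


class Role(str, Enum):
    target = "target"
    internal_standard = "internal_standard"


class Rank(str, Enum):
    quantifier = "quantifier"
    qualifier = "qualifier"


class Matrix(str, Enum):
    muscle = "muscle"
    milk = "milk"


class TransitionRecord(BaseModel):
    """One monitored SRM transition.

    ``precursor_mz > product_mz`` is deliberately NOT enforced: doubly
    charged precursors may fragment to singly charged products of higher
    m/z (e.g. spiramycin 422.3 -> 702.4).
    """

    model_config = ConfigDict(frozen=True)

    analyte: str
    role: Role
    matrices: frozenset[Matrix]
    retention_time: float
    adduct: str
    precursor_mz: float
    product_mz: float
    collision_energy: float
    rank: Rank

    @field_validator("retention_time", "collision_energy", "precursor_mz", "product_mz")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("matrices")
    @classmethod
    def _nonempty(cls, v: frozenset[Matrix]) -> frozenset[Matrix]:
        if not v:
            raise ValueError("at least one matrix required")
        return v


class MethodTable(BaseModel):
    """The full acquisition design: all monitored transitions.

    Invariants: every target analyte carries exactly two transitions
    (quantifier + qualifier); internal standards carry one or two.
    """

    model_config = ConfigDict(frozen=True)

    records: tuple[TransitionRecord, ...]

    @model_validator(mode="after")
    def _check_transition_counts(self) -> "MethodTable":
        seen: set[tuple[str, float, float]] = set()
        for rec in self.records:
            key = (rec.analyte, rec.precursor_mz, rec.product_mz)
            if key in seen:
                raise DuplicateTransitionError(
                    f"duplicate transition {rec.analyte} "
                    f"{rec.precursor_mz} -> {rec.product_mz}"
                )
            seen.add(key)
        for name in self.analytes(Role.target):
            n = len(self.transitions_for(name))
            if n != 2:
                raise ValueError(f"target {name!r} has {n} transitions, expected 2")
        for name in self.analytes(Role.internal_standard):
            n = len(self.transitions_for(name))
            if n not in (1, 2):
                raise ValueError(
                    f"internal standard {name!r} has {n} transitions, expected 1-2"
                )
        return self

    def __len__(self) -> int:
        return len(self.records)

    def analytes(self, role: Role | None = None) -> list[str]:
        """Unique analyte names, in table order, optionally filtered by role."""
        out: list[str] = []
        for rec in self.records:
            if role is not None and rec.role != role:
                continue
            if rec.analyte not in out:
                out.append(rec.analyte)
        return out

    @property
    def target_analytes(self) -> list[str]:
        return self.analytes(Role.target)

    @property
    def internal_standards(self) -> list[str]:
        return self.analytes(Role.internal_standard)

    def transitions_for(self, analyte: str) -> list[TransitionRecord]:
        return [r for r in self.records if r.analyte == analyte]

    def quantifier(self, analyte: str) -> TransitionRecord:
        for r in self.transitions_for(analyte):
            if r.rank is Rank.quantifier:
                return r
        raise KeyError(f"no quantifier transition for {analyte!r}")

    def analytes_in(self, matrix: Matrix | str) -> list[str]:
        matrix = Matrix(matrix)
        return [
            a
            for a in self.target_analytes
            if matrix in self.transitions_for(a)[0].matrices
        ]

    def retention_time(self, analyte: str) -> float:
        return self.transitions_for(analyte)[0].retention_time

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "analyte": r.analyte,
                "role": r.role.value,
                "matrices": ";".join(
                    sorted(m.value for m in r.matrices)
                ),
                "rt_min": r.retention_time,
                "adduct": r.adduct,
                "precursor_mz": r.precursor_mz,
                "product_mz": r.product_mz,
                "ce_ev": r.collision_energy,
                "rank": r.rank.value,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    def to_csv(self, path, dialect: str = "csv") -> None:
        sep = "\t" if dialect == "tsv" else ","
        self.to_frame().to_csv(path, sep=sep, index=False)


class InterferencePair(BaseModel):
    """Two target analytes at risk of nominal-mass SRM cross-talk."""

    model_config = ConfigDict(frozen=True)

    analyte_a: str
    analyte_b: str
    shared_precursor: bool
    shared_transitions: tuple[tuple[float, float], ...]
    delta_rt: float
    risk_note: str

    @model_validator(mode="after")
    def _check(self) -> "InterferencePair":
        if self.delta_rt < 0:
            raise ValueError("delta_rt must be >= 0")
        if not (self.shared_precursor or self.shared_transitions):
            raise ValueError("pair must share at least one dimension")
        return self


def parse_method_table(path, dialect: str = "csv") -> MethodTable:
    """Read an acquisition table from CSV/TSV into a validated MethodTable."""
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"method table missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            numeric = {
                k: float(row[k]) for k in ("rt_min", "precursor_mz", "product_mz", "ce_ev")
            }
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric value in row {i}: {exc}") from exc
        records.append(
            TransitionRecord(
                analyte=row["analyte"].strip(),
                role=Role(row["role"].strip()),
                matrices=frozenset(
                    Matrix(m.strip()) for m in row["matrices"].split(";")
                ),
                retention_time=numeric["rt_min"],
                adduct=row["adduct"].strip(),
                precursor_mz=numeric["precursor_mz"],
                product_mz=numeric["product_mz"],
                collision_energy=numeric["ce_ev"],
                rank=Rank(row["rank"].strip()),
            )
        )
    return MethodTable(records=tuple(records))


def screen_interferences(
    table: MethodTable, rt_window: float = 0.3, mz_tol: float = 0.5
) -> list[InterferencePair]:
    """Flag target-analyte pairs at risk of precursor cross-talk.

    A pair is flagged when the analytes co-elute (|dRT| <= ``rt_window``)
    and their precursor ions collide within ``mz_tol`` on the nominal-mass
    axis (a unit-resolution quadrupole cannot separate them, regardless of
    charge state). Any monitored product m/z the two share within the same
    tolerance is annotated. Sorted by increasing dRT.
    """
    if rt_window <= 0:
        raise ValueError("rt_window must be > 0")
    if mz_tol < 0:
        raise ValueError("mz_tol must be >= 0")
    pairs: list[InterferencePair] = []
    for a, b in itertools.combinations(table.target_analytes, 2):
        trans_a = table.transitions_for(a)
        trans_b = table.transitions_for(b)
        delta_rt = abs(trans_a[0].retention_time - trans_b[0].retention_time)
        if delta_rt > rt_window:
            continue
        prec_close = any(
            abs(ta.precursor_mz - tb.precursor_mz) <= mz_tol
            for ta in trans_a
            for tb in trans_b
        )
        if not prec_close:
            continue
        shared_products = tuple(
            sorted(
                {
                    (ta.precursor_mz, ta.product_mz)
                    for ta in trans_a
                    for tb in trans_b
                    if abs(ta.product_mz - tb.product_mz) <= mz_tol
                }
            )
        )
        pairs.append(
            InterferencePair(
                analyte_a=a,
                analyte_b=b,
                shared_precursor=True,
                shared_transitions=shared_products,
                delta_rt=round(delta_rt, 6),
                risk_note=(
                    f"precursors within {mz_tol} m/z, co-elution within "
                    f"{rt_window} min: quantifier cross-talk possible"
                ),
            )
        )
    pairs.sort(key=lambda p: (p.delta_rt, p.analyte_a, p.analyte_b))
    return pairs


def estimate_crosstalk_bias(area_a: float, area_b: float, shared: bool) -> float:
    """Multiplicative over-estimation of analyte a when b bleeds into its
    quantifier transition: (A_a + A_b) / A_a. Returns 1 when nothing is
    shared."""
    if area_a < 0 or area_b < 0:
        raise ValueError("areas must be >= 0")
    if not shared:
        return 1.0
    if area_a == 0:
        raise ZeroDivisionError("quantifier area of the affected analyte is zero")
    return (area_a + area_b) / area_a


def interference_report(pairs: Iterable[InterferencePair]) -> pd.DataFrame:
    rows = [
        {
            "analyte_a": p.analyte_a,
            "analyte_b": p.analyte_b,
            "delta_rt": p.delta_rt,
            "shared_precursor": p.shared_precursor,
            "shared_transitions": "|".join(
                f"{prec}>{prod}" for prec, prod in p.shared_transitions
            ),
            "risk_note": p.risk_note,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "analyte_a",
            "analyte_b",
            "delta_rt",
            "shared_precursor",
            "shared_transitions",
            "risk_note",
        ],
    )
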