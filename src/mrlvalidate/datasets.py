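"""Bundled fixtures: acquisition table, performance surface, MRLs, PT records.

All fixtures are small editable CSVs shipped inside the package:

* ``srm_method_table.csv`` — the 64-analyte SRM acquisition design (two
  transitions per target, eight internal standards).
* ``performance_table.csv`` — the reference per-analyte validation summary
  (pooled CVs, recovery, matrix effect, fitness class) used as ground
  truths when simulating realistic scenarios.
* ``mrl_subset.csv`` — a small editable subset of regulatory maximum
  residue limits, enough to exercise the CCalpha/CCbeta machinery.
* ``pt_records.csv`` — proficiency-test materials with consensus values and
  acceptability ranges for both instrument platforms.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .method_table import MethodTable, parse_method_table


def _data_path(name: str):
    return resources.files("mrlvalidate.data").joinpath(name)


def method_table_path():
    return _data_path("srm_method_table.csv")


def load_method_table() -> MethodTable:
    with resources.as_file(method_table_path()) as p:
        return parse_method_table(p)


def load_performance_table() -> pd.DataFrame:
    with resources.as_file(_data_path("performance_table.csv")) as p:
        return pd.read_csv(p)


def load_mrl_table() -> pd.DataFrame:
    with resources.as_file(_data_path("mrl_subset.csv")) as p:
        return pd.read_csv(p)


def mrl_lookup(matrix: str) -> dict[str, float]:
    """analyte -> MRL (ug/kg) for one matrix, from the bundled subset."""
    df = load_mrl_table()
    sub = df[df["matrix"] == matrix]
    return dict(zip(sub["analyte"], sub["mrl_ug_kg"].astype(float)))


def pt_records_path():
    return _data_path("pt_records.csv")
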