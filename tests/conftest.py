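import pandas as pd
import pytest

from mrlvalidate.datasets import load_method_table


@pytest.fixture(scope="session")
def method_table():
    return load_method_table()


@pytest.fixture()
def tiny_table_csv(tmp_path):
    """A minimal two-analyte acquisition table on disk."""
    path = tmp_path / "table.csv"
    path.write_text(
        "analyte,role,matrices,rt_min,adduct,precursor_mz,product_mz,ce_ev,rank\n"
        "drug A,target,muscle;milk,5.0,[M + H]+,300.1,100.0,20,quantifier\n"
        "drug A,target,muscle;milk,5.0,[M + H]+,300.1,150.0,25,qualifier\n"
        "drug B,target,muscle,5.1,[M + H]+,300.2,120.0,20,quantifier\n"
        "drug B,target,muscle,5.1,[M + H]+,300.2,150.1,25,qualifier\n"
    )
    return path


def make_level_frame(levels_areas):
    """Tidy (level, area) frame from {level: [areas]}."""
    rows = [
        {"level": level, "area": a}
        for level, areas in levels_areas.items()
        for a in areas
    ]
    return pd.DataFrame(rows)
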