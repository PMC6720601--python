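"""Score the re-tested proficiency-test materials for both platforms.

Evaluates every stored PT material against its organizer-assigned consensus
value and acceptability range, for the triple-quadrupole results and the
high-resolution results, with an advisory z-score reconstructed from the
quarter-range sigma. Writes results/pt_evaluation.csv.
"""

from pathlib import Path

import pandas as pd

from mrlvalidate.datasets import pt_records_path
from mrlvalidate.pt_eval import load_pt_records, pt_summary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    frames = []
    for method in ("qqq", "orbitrap"):
        df = pt_summary(load_pt_records(pt_records_path(), method=method))
        df.insert(0, "method", method)
        frames.append(df)
        evaluable = df[df["in_range"].notna()]
        n_fail = int((evaluable["in_range"] == False).sum())  # noqa: E712
        print(
            f"{method}: {len(evaluable)} evaluable materials, "
            f"{n_fail} outside the acceptability range"
        )
        for _, row in evaluable[evaluable["in_range"] == False].iterrows():  # noqa: E712
            print(
                f"  {row.sample_code} {row.analyte} in {row.matrix}: "
                f"found {row.found if pd.notna(row.found) else 'ND'}, "
                f"consensus {row.consensus}"
            )
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(out / "pt_evaluation.csv", index=False)
    print(f"wrote {out / 'pt_evaluation.csv'}")


if __name__ == "__main__":
    main()
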