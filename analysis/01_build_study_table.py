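"""Build the synthetic benchmark study table.

The original row-level study-factor table is not redistributable, so the
analysis runs on a deterministic synthetic stand-in that reproduces the
published corpus structure exactly where it is printed: 48 studies, 61
classification-model rows, and the medical-question x cross-validation cell
counts with their mean accuracies.  This script materializes that table to
``data/synthetic_study_table.csv`` and prints the structure checks.

Run from the repository root:  python analysis/01_build_study_table.py
"""

from pathlib import Path

from accmeta.meta_regression import crosstab_summary
from accmeta.study_table import load_study_table, write_study_table
from accmeta.synthetic_data import make_synthetic_benchmark_table

OUT = Path(__file__).resolve().parents[1] / "data" / "synthetic_study_table.csv"


def main() -> None:
    records = make_synthetic_benchmark_table()
    OUT.parent.mkdir(exist_ok=True)
    write_study_table(records, OUT)
    reread = load_study_table(OUT)
    assert [r.model_id for r in reread] == [r.model_id for r in records]
    print(f"wrote {OUT}")
    print(f"rows: {len(records)}  studies: {len({r.study_id for r in records})}")
    print("\ncross-validation x medical-question cells (count, mean accuracy):")
    print(crosstab_summary(records, "cv_technique", "medical_question")
          .to_string(index=False))


if __name__ == "__main__":
    main()
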