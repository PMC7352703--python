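"""Library-level read accounting for the six-library worked example.

Sums the per-library raw / trimmed / mapped read counts from the bundled
sequencing summary and converts them to read-pair totals.
"""

import json
from pathlib import Path

from endotx import data_path
from endotx.expression_de import QcSummary, qc_totals

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    qc = QcSummary.from_tsv(data_path("library_qc.tsv"))
    totals = qc_totals(qc)
    OUT.mkdir(exist_ok=True)
    with open(OUT / "qc_totals.json", "w") as fh:
        json.dump(totals, fh, indent=1)
    print("read-pair totals over the six libraries:")
    for stat, value in totals.items():
        print(f"  {stat:>18}: {value:,}")


if __name__ == "__main__":
    main()
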