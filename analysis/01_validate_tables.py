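#!/usr/bin/env python
"""Load the packaged measurement tables and audit their internal consistency.

Recomputes every derivable column (%NC from the area cells, EQ from volume
and body mass, surface additivity) and writes a per-record report. The known
outcome on a fresh checkout: ~98% of %NC cells and ~99% of EQ cells
reproduce, and the Equus occidentalis %NC cell (printed 85.19, recomputed
58.66) is flagged as irreconcilable with its own measurements.
"""

import csv
from pathlib import Path

from paleoneuro import dataset

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table1 = dataset.load_table("table1_mammals")
    counts = {s.value: sum(1 for r in table1 if r.section == s) for s in dataset.Section}
    print(f"loaded {len(table1)} specimens: {counts}")

    reports = dataset.validate_records(table1)
    out = OUT / "validation_report.csv"
    with open(out, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record", "check", "status", "detail"])
        for rep in reports:
            for c in rep.checks:
                writer.writerow([rep.record_label, c.check_name, c.status, c.detail])

    for name in ("pctNC", "EQ", "additivity"):
        done = [c for rep in reports for c in rep.checks
                if c.check_name == name and c.status != "skipped_missing"]
        n_pass = sum(1 for c in done if c.status == "pass")
        print(f"  {name}: {n_pass}/{len(done)} printed cells reproduce")
    failing = [rep.record_label for rep in reports if rep.failed]
    print(f"  records with at least one inconsistent cell: {len(failing)}")
    for label in failing:
        print(f"    - {label}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
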