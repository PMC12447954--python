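#!/usr/bin/env python
"""Endocast surface area versus volume: how fast does surface accumulate?

Fits S = c * E**k in log-log space over all table rows with both
measurements and compares k against the geometric reference 2/3 (a smooth
solid). Also fits a 2/3-pinned reference and reports each specimen's
convolutedness index relative to it. Note the fitted endocast exponent sits
*at* the geometric value (~0.66): an endocast's surface misses the cortex
buried in sulci, so it scales like a smooth solid even though true cortical
surface in living mammals scales near 0.91.
"""

import csv
import json
from pathlib import Path

from scipy.stats import spearmanr

from paleoneuro import dataset, scaling

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table1 = dataset.load_table("table1_mammals")
    usable, dropped = dataset.require_fields(table1, "E", "S")
    pairs = [(r.E, r.S) for r in usable]
    print(f"{len(pairs)} specimens with S and E ({dropped} rows lack one)")

    fit = scaling.fit_surface_volume(pairs)
    print(f"S = {fit.coefficient:.2f} * E^{fit.exponent:.4f} (r = {fit.r:.3f})")
    print(f"geometric reference exponent: {fit.geometric_reference_exponent:.4f}")

    reference = scaling.geometric_reference(pairs)
    indexed = [
        (r.label, scaling.convolutedness_index(r.S, r.E, reference))
        for r in usable
    ]
    rho = spearmanr([i for _, i in indexed], [r.E for r in usable]).statistic
    print(f"convolutedness index vs volume: Spearman rho = {rho:.3f}")
    top = sorted(indexed, key=lambda t: -t[1])[:3]
    for label, idx in top:
        print(f"  most convoluted relative to trend: {label} (index {idx:.2f})")

    with open(OUT / "convolutedness.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record", "convolutedness_index"])
        for label, idx in indexed:
            writer.writerow([label, repr(idx)])
    (OUT / "scaling.json").write_text(json.dumps({
        "exponent": fit.exponent, "coefficient": fit.coefficient,
        "r": fit.r, "n": fit.n,
        "reference_coefficient": reference.coefficient,
        "spearman_index_vs_volume": rho,
    }, indent=2))
    print(f"wrote {OUT / 'scaling.json'} and {OUT / 'convolutedness.csv'}")


if __name__ == "__main__":
    main()
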