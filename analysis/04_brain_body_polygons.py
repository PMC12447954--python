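#!/usr/bin/env python
"""Brain-body convex polygons and the mammal-reptile boundary.

Builds minimum convex polygons per table section in (log10 P, log10 E)
space, then tests the boundary question: does the least-encephalized mammal
in the table (the Paleocene Arctocyon, 7.14 ml brain at 16.1 kg) fall above
a reptile-grade polygon? The reptile polygon uses a synthetic reptile cloud
(the published per-specimen reptile data are not printed) anchored at the
two printed crocodilian maxima, and is also extended to dinosaur body sizes
(log10 P = 7) at the slope of its last upper edge.
"""

import json
from pathlib import Path

from paleoneuro import dataset, hullspace, synthetic_data

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table1 = dataset.load_table("table1_mammals")

    polygons = {}
    for section in dataset.Section:
        pts = [(r.P, r.E) for r in table1
               if r.section == section and r.P is not None and r.E is not None]
        polygons[section.value] = hullspace.minimum_convex_polygon(pts, label=section.value)
        print(f"{section.value}: {len(pts)} points, "
              f"{len(polygons[section.value].vertices)} hull vertices")

    reptiles = hullspace.minimum_convex_polygon(
        synthetic_data.reptile_brain_body_points(seed=0), label="reptiles")
    extended = hullspace.extend_polygon(reptiles, 7.0)
    polygons["reptiles"] = reptiles
    polygons["reptiles-extended"] = extended

    arcto = next(r for r in table1 if r.species == "Arctocyon primaevus")
    for label in ("reptiles", "reptiles-extended"):
        verdict = hullspace.classify_point((arcto.P, arcto.E), polygons[label])
        print(f"Arctocyon ({arcto.E} ml, {arcto.P:g} g) vs {label}: {verdict.value}")

    payload = {
        label: {"label": poly.label,
                "vertices_log10": [list(v) for v in poly.vertices]}
        for label, poly in polygons.items()
    }
    out = OUT / "polygons.json"
    out.write_text(json.dumps(payload, indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
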