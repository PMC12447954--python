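#!/usr/bin/env python
"""Neocorticalization through geologic time and against encephalization.

Fits the OLS line of %NC on age (Ma) over all table rows with both
quantities, predicts the present-day and 60-Ma averages, and repeats the fit
without sub-1-Ma fossils (the tar-pit material is effectively modern). Then
bins %NC by EQ to show the saturation of neocortical expansion near 80%.
"""

import json
from pathlib import Path

import numpy as np

from paleoneuro import dataset, neocortex

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table1 = dataset.load_table("table1_mammals")

    fit = neocortex.trend_vs_time(table1, predict_at=(0.0, -60.0))
    print(f"trend over all usable rows (n = {fit.n}):")
    print(f"  slope {fit.slope:.3f} %/Ma  ->  {fit.slope * 10:.1f} points per 10 Myr")
    for age, pct in fit.predictions:
        print(f"  predicted average %NC at {age:g} Ma: {pct:.1f}%")

    trimmed = neocortex.trend_vs_time(table1, predict_at=(0.0, -60.0),
                                      exclude_recent_Ma=1.0)
    print(f"without sub-1-Ma fossils (n = {trimmed.n}): slope {trimmed.slope:.3f} %/Ma")

    profile = neocortex.nc_vs_eq_profile(table1)
    print(f"maximum %NC in the table (recomputed): {profile.max_pct:.2f}%")
    occupied = [(e, m) for e, m in zip(profile.bin_edges, profile.bin_means)
                if not np.isnan(m)]
    print("mean %NC by EQ bin:")
    for edge, mean in occupied:
        print(f"  EQ [{edge:.1f}, {edge + 0.5:.1f}): {mean:.1f}%")

    payload = {
        "all_rows": {"slope": fit.slope, "intercept": fit.intercept,
                     "r": fit.r, "n": fit.n,
                     "predictions": dict(fit.predictions)},
        "excluding_sub_1Ma": {"slope": trimmed.slope, "intercept": trimmed.intercept,
                              "r": trimmed.r, "n": trimmed.n},
        "profile": {"bin_edges": profile.bin_edges,
                    "bin_means": [None if np.isnan(m) else m for m in profile.bin_means],
                    "max_pct": profile.max_pct,
                    "eq_at_plateau": profile.eq_at_plateau},
    }
    out = OUT / "nc_trend.json"
    out.write_text(json.dumps(payload, indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
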