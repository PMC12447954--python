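"""Neocorticalization: the fraction of endocast surface that is neocortex.

The rhinal fissure is the one neocortex boundary reliably visible on an
endocast, so neocorticalization is measured as the percentage of endocast
surface area dorsal to it:

    %NC = 100 * NC / (S - OB)

with olfactory bulbs excluded from the denominator because bulbs are often
broken or missing from casts. This module computes the ratio, its trend
over geologic time (an OLS line of %NC on age in Ma, negative = past), and
its profile against encephalization (binned means of %NC by EQ, which
saturate near 80% once EQ reaches about 2).

Recomputed %NC is preferred over the table's printed column wherever NC and
S-OB are available, so a known-bad printed cell never propagates; the
printed value is the fallback when areas are missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from . import allometry
from .dataset import SpecimenRecord
from .errors import DomainError

#: Default width of EQ bins in the neocorticalization-vs-EQ profile.
DEFAULT_BIN_WIDTH = 0.5

#: Successive bin means closer than this (percentage points) count as flat.
DEFAULT_PLATEAU_TOL = 2.0


@dataclass(frozen=True)
class TrendFit:
    """OLS of %NC on geologic age: slope (%/Ma), intercept (% at 0 Ma)."""

    slope: float
    intercept: float
    r: float
    n: int
    predictions: tuple[tuple[float, float], ...] = ()

    def predict(self, age_Ma: float) -> float:
        return self.intercept + self.slope * age_Ma


@dataclass(frozen=True)
class NcEqProfile:
    """Binned %NC means along the EQ axis, with the observed plateau."""

    bin_edges: tuple[float, ...]
    bin_means: tuple[float, ...]  # NaN for empty bins
    max_pct: float
    eq_at_plateau: float | None


def pct_neocortex(NC: float, S_minus_OB: float) -> float:
    """%NC = 100 * NC / (S - OB); NC may not exceed the total surface."""
    if not NC > 0 or not S_minus_OB > 0:
        raise DomainError("areas must be positive")
    if NC > S_minus_OB:
        raise DomainError(
            f"neocortex area {NC} exceeds total surface {S_minus_OB}: "
            "mis-paired measurements"
        )
    return 100.0 * NC / S_minus_OB


def pct_neocortex_of(record: SpecimenRecord) -> float | None:
    """Recomputed %NC when areas allow it, else the printed column, else None."""
    if record.NC is not None and record.S_minus_OB is not None:
        return pct_neocortex(record.NC, record.S_minus_OB)
    return record.pctNC_reported


def trend_vs_time(
    records: Sequence[SpecimenRecord],
    predict_at: Sequence[float] = (),
    exclude_recent_Ma: float | None = None,
    exclude: Sequence[str] = (),
) -> TrendFit:
    """OLS of %NC on geologic age over all rows with both quantities.

    ``exclude_recent_Ma`` drops fossils younger than the given absolute age
    (the tar-pit material is nearly extant and can be argued to belong with
    the 0-Ma column); ``exclude`` drops records by label (e.g. rows whose
    printed cells failed validation). Predictions are evaluated exactly on
    the fitted line at the requested ages.
    """
    pts = []
    for rec in records:
        pct = pct_neocortex_of(rec)
        if pct is None or rec.age_Ma is None or rec.label in exclude:
            continue
        if (
            exclude_recent_Ma is not None
            and rec.age_Ma != 0
            and abs(rec.age_Ma) < exclude_recent_Ma
        ):
            continue
        pts.append((rec.age_Ma, pct))
    if len(pts) < 3:
        raise DomainError(f"need >= 3 rows with %NC and age, got {len(pts)}")
    x = np.asarray([a for a, _ in pts])
    y = np.asarray([p for _, p in pts])
    res = stats.linregress(x, y)
    fit = TrendFit(float(res.slope), float(res.intercept), float(res.rvalue), len(pts))
    if predict_at:
        fit = TrendFit(
            fit.slope, fit.intercept, fit.r, fit.n,
            tuple((float(a), fit.predict(a)) for a in predict_at),
        )
    return fit


def nc_vs_eq_profile(
    records: Sequence[SpecimenRecord],
    bin_width: float = DEFAULT_BIN_WIDTH,
    plateau_tol: float = DEFAULT_PLATEAU_TOL,
) -> NcEqProfile:
    """Mean %NC in equal-width EQ bins, the overall maximum, and the plateau.

    EQ is recomputed (b = 0.12, alpha = 2/3) when E and P are present,
    falling back to the printed EQ column. The plateau edge is the smallest
    bin edge beyond which successive non-empty bin means differ by less than
    ``plateau_tol`` percentage points; ``None`` when the profile never
    flattens.
    """
    if not bin_width > 0:
        raise DomainError("bin_width must be positive")
    pts = []
    for rec in records:
        pct = pct_neocortex_of(rec)
        if pct is None:
            continue
        if rec.E is not None and rec.P is not None:
            quotient = allometry.eq(rec.E, rec.P).eq
        else:
            quotient = rec.EQ_reported
        if quotient is None:
            continue
        pts.append((quotient, pct))
    if len(pts) < 3:
        raise DomainError(f"need >= 3 rows with %NC and EQ, got {len(pts)}")

    quotients = np.asarray([q for q, _ in pts])
    pcts = np.asarray([p for _, p in pts])
    n_bins = max(1, int(math.ceil(quotients.max() / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    which = np.clip(np.digitize(quotients, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    for k in range(n_bins):
        sel = which == k
        if sel.any():
            means[k] = pcts[sel].mean()

    eq_at_plateau = _plateau_edge(edges, means, plateau_tol)
    return NcEqProfile(
        bin_edges=tuple(float(e) for e in edges),
        bin_means=tuple(float(m) for m in means),
        max_pct=float(pcts.max()),
        eq_at_plateau=eq_at_plateau,
    )


def _plateau_edge(
    edges: np.ndarray, means: np.ndarray, tol: float
) -> float | None:
    occupied = [k for k, m in enumerate(means) if not np.isnan(m)]
    if len(occupied) < 2:
        return float(edges[occupied[0]]) if occupied else None
    for start_pos, k in enumerate(occupied[:-1]):
        diffs = [
            abs(means[occupied[j + 1]] - means[occupied[j]])
            for j in range(start_pos, len(occupied) - 1)
        ]
        if all(d < tol for d in diffs):
            return float(edges[k])
    return None
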