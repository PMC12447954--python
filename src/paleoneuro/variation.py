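"""Within-species variation statistics.

How much do endocasts of one species vary? The summary statistic is the
coefficient of variation, CV = SD/mean, with the sample (n-1) standard
deviation. For endocast volume a CV near 10% recurs across mammal species,
which is what justifies letting a single specimen stand for its species in
between-species comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

from .dataset import SpecimenRecord
from .errors import DomainError


@dataclass(frozen=True)
class CVSummary:
    """Mean, sample SD (n-1) and coefficient of variation for one variable."""

    variable: str
    n: int
    mean: float
    sd: float

    @property
    def cv(self) -> float:
        return self.sd / self.mean

    @property
    def cv_pct(self) -> float:
        return 100.0 * self.cv


def cv_summary(values: Sequence[float], variable: str = "") -> CVSummary:
    """Mean, sample SD and CV of positive measurements (n >= 2)."""
    n = len(values)
    if n < 2:
        raise DomainError(f"need >= 2 values, got {n}")
    if any(v <= 0 for v in values):
        raise DomainError("all measurements must be positive")
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return CVSummary(variable=variable, n=n, mean=mean, sd=sd)


#: Extractors for the variables a within-species table can summarize.
#: ``nc_over_S`` is the neocortex:surface ratio (bulbs were absent from
#: these casts, so the denominator is the total surface S).
VARIABLE_EXTRACTORS: dict[str, Callable[[SpecimenRecord], float | None]] = {
    "E": lambda r: r.E,
    "S": lambda r: r.S,
    "NC": lambda r: r.NC,
    "S_minus_OB": lambda r: r.S_minus_OB,
    "OB": lambda r: r.OB,
    "L": lambda r: r.L,
    "P": lambda r: r.P,
    "nc_over_S": lambda r: (
        r.NC / r.S if r.NC is not None and r.S is not None else None
    ),
}


def variation_table(
    records: Sequence[SpecimenRecord], variables: Sequence[str]
) -> list[CVSummary]:
    """One CVSummary per named variable, over records where it is present."""
    out = []
    for name in variables:
        try:
            extract = VARIABLE_EXTRACTORS[name]
        except KeyError:
            raise DomainError(
                f"unknown variable {name!r}; known: {sorted(VARIABLE_EXTRACTORS)}"
            ) from None
        values = [v for v in (extract(r) for r in records) if v is not None]
        if len(values) < 2:
            raise DomainError(
                f"variable {name!r} present in {len(values)} records; need >= 2"
            )
        out.append(cv_summary(values, variable=name))
    return out
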