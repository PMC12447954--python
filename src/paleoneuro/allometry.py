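"""Brain-body allometry and the encephalization quotient.

Across mammals, brain size E (ml) scales with body mass P (g) as a power
law, E = b * P**alpha, which is linear in log-log space:

    log10 E = alpha * log10 P + log10 b

The encephalization quotient (EQ) of a specimen is the ratio of its observed
brain size to the size this reference allometry expects at its body mass,

    EQ = E / (b * P**alpha),

with the classical theoretical choices alpha = 2/3 (a surface:volume
exponent: the brain maps the body's 2D sensory surface) and b = 0.12.
EQ = 1 means exactly as much brain as expected; EQ = 5.8 (a modern human
endocast) means 5.8 times as much.

All quantities are cgs (ml and g): the intercept b is unit-dependent, so
EQs computed in other unit systems are meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import SpecimenRecord
from .errors import DegenerateFitError, DomainError

#: Theoretical allometric exponent (surface:volume), applied as the exact
#: double-precision fraction 2/3, never a decimal truncation like 0.67.
THEORETICAL_ALPHA = 2.0 / 3.0

#: Classical reference intercept for mammals in cgs units; recoverable from
#: the packaged table's printed EQ column via :func:`derive_b`.
DEFAULT_B = 0.12


@dataclass(frozen=True)
class AllometricModel:
    """A fitted log10 E ~ log10 P line: slope, intercept, correlation, n."""

    alpha: float
    log10_b: float
    r: float
    n: int

    @property
    def b(self) -> float:
        return 10.0 ** self.log10_b

    def predict_log10E(self, log10_P: float) -> float:
        return self.log10_b + self.alpha * log10_P

    def predict_E(self, P: float) -> float:
        return self.b * P ** self.alpha


@dataclass(frozen=True)
class EQResult:
    record_id: str
    expected_E: float
    eq: float


def body_mass_from_length(L: float) -> float:
    """Body mass (g) from body length (cm): P = 0.021 * L**3.03.

    The near-cubic exponent reflects geometric similarity of body shapes;
    the formula is exposed for reference and is never used to back-fill
    missing body masses (the table's L column is endocast length, a
    different quantity).
    """
    if not L > 0:
        raise DomainError(f"body length must be positive, got {L}")
    return 0.021 * L ** 3.03


def fit_loglog(
    pairs: Sequence[tuple[float, float]], method: str = "ols"
) -> AllometricModel:
    """Fit log10 E on log10 P for (P, E) pairs.

    ``method="ols"`` (default) is ordinary least squares, matching
    bivariate-regression practice for these data; ``method="rma"`` gives the
    reduced-major-axis slope (OLS slope / |r|) for comparison.
    """
    if len(pairs) < 2:
        raise DomainError(f"need at least 2 pairs, got {len(pairs)}")
    P = np.asarray([p for p, _ in pairs], dtype=float)
    E = np.asarray([e for _, e in pairs], dtype=float)
    if np.any(P <= 0) or np.any(E <= 0):
        raise DomainError("all masses and volumes must be positive")
    x, y = np.log10(P), np.log10(E)
    if np.allclose(x, x[0]):
        raise DegenerateFitError("all body masses identical: slope undefined")
    if method not in ("ols", "rma"):
        raise DomainError(f"unknown regression method {method!r}")
    if np.allclose(y, y[0]):
        # horizontal line: scipy returns slope 0 with r = nan
        return AllometricModel(0.0, float(y[0]), 0.0, len(pairs))
    res = stats.linregress(x, y)
    slope, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    if method == "rma":
        if abs(r) < 1e-12:
            raise DegenerateFitError("RMA slope undefined at r = 0")
        sign = 1.0 if slope >= 0 else -1.0
        slope = sign * float(np.std(y, ddof=1) / np.std(x, ddof=1))
        intercept = float(np.mean(y) - slope * np.mean(x))
    return AllometricModel(slope, intercept, r, len(pairs))


def eq(
    E: float,
    P: float,
    b: float = DEFAULT_B,
    alpha: float = THEORETICAL_ALPHA,
    record_id: str = "",
) -> EQResult:
    """Encephalization quotient EQ = E / (b * P**alpha), cgs units only."""
    if not E > 0:
        raise DomainError(f"brain volume must be positive, got {E}")
    if not P > 0:
        raise DomainError(f"body mass must be positive, got {P}")
    if not b > 0:
        raise DomainError(f"intercept b must be positive, got {b}")
    expected = b * P ** alpha
    return EQResult(record_id=record_id, expected_E=expected, eq=E / expected)


def eq_for_records(
    records: Sequence[SpecimenRecord],
    b: float = DEFAULT_B,
    alpha: float = THEORETICAL_ALPHA,
) -> list[EQResult]:
    """EQ for every record with both E and P present (others are skipped)."""
    return [
        eq(r.E, r.P, b=b, alpha=alpha, record_id=r.label)
        for r in records
        if r.E is not None and r.P is not None
    ]


def derive_b(
    records: Sequence[SpecimenRecord],
    alpha: float = THEORETICAL_ALPHA,
    min_rows: int = 10,
) -> float:
    """Back-solve the reference intercept b from a table's printed EQ column.

    For each row with E, P and a printed EQ, b = E / (EQ * P**alpha); the
    median over rows is robust to the 2-decimal rounding of the printed
    quotients. Requires at least ``min_rows`` complete rows (default 10; a
    noiseless single-row inversion is exact, so tests may lower it).
    """
    values = [
        r.E / (r.EQ_reported * r.P ** alpha)
        for r in records
        if r.E is not None and r.P is not None
        and r.EQ_reported is not None and r.EQ_reported > 0
    ]
    if len(values) < min_rows:
        raise DomainError(
            f"need >= {min_rows} rows with E, P and reported EQ, got {len(values)}"
        )
    return float(np.median(values))
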