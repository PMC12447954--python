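"""Surface-area-versus-volume scaling and a convolutedness index.

A smooth solid's surface grows as volume**(2/3). Mammal brains beat that
exponent decisively — cortical surface grows roughly as volume**0.9 —
because bigger brains are disproportionately more folded. Fitting

    log10 S = exponent * log10 E + log10(coefficient)

by OLS quantifies this; the gap between the fitted exponent and the
geometric reference 2/3 measures how fast folding accumulates with size.

The convolutedness index of a single specimen compares its surface to a
2/3-pinned reference trend fitted to the dataset itself (not to a sphere):
index > 1 means more folded than a smooth-scaling brain of that size on
this dataset's trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import allometry
from .errors import DomainError, StateError

GEOMETRIC_EXPONENT = 2.0 / 3.0


@dataclass(frozen=True)
class ScalingFit:
    """S = coefficient * E**exponent fitted in log10 space."""

    exponent: float
    coefficient: float
    r: float
    n: int
    geometric_reference_exponent: float = GEOMETRIC_EXPONENT

    def predict(self, volume: float) -> float:
        return self.coefficient * volume ** self.exponent


def fit_surface_volume(pairs: Sequence[tuple[float, float]]) -> ScalingFit:
    """OLS of log10 S on log10 E over (E, S) pairs (>= 3 of them)."""
    if len(pairs) < 3:
        raise DomainError(f"need >= 3 (E, S) pairs, got {len(pairs)}")
    model = allometry.fit_loglog(pairs)  # same log-log OLS machinery
    return ScalingFit(
        exponent=model.alpha,
        coefficient=10.0 ** model.log10_b,
        r=model.r,
        n=model.n,
    )


def geometric_reference(pairs: Sequence[tuple[float, float]]) -> ScalingFit:
    """Least-squares fit of S = c * E**(2/3) with the exponent pinned.

    With the exponent fixed, the optimal log10 c is the mean log residual,
    log10 c = mean(log10 S - (2/3) log10 E).
    """
    if len(pairs) < 1:
        raise DomainError("need at least one (E, S) pair")
    E = np.asarray([e for e, _ in pairs], dtype=float)
    S = np.asarray([s for _, s in pairs], dtype=float)
    if np.any(E <= 0) or np.any(S <= 0):
        raise DomainError("volumes and surfaces must be positive")
    log_c = float(np.mean(np.log10(S) - GEOMETRIC_EXPONENT * np.log10(E)))
    r = 0.0
    if len(pairs) >= 3:
        r = fit_surface_volume(pairs).r
    return ScalingFit(
        exponent=GEOMETRIC_EXPONENT,
        coefficient=10.0 ** log_c,
        r=r,
        n=len(pairs),
    )


def convolutedness_index(S: float, E: float, reference: ScalingFit) -> float:
    """S relative to the 2/3-pinned reference trend at volume E.

    Values above 1 mean the specimen is more folded than the dataset's
    smooth-scaling trend predicts at its size.
    """
    if reference is None or not isinstance(reference, ScalingFit):
        raise StateError("reference must be a fitted ScalingFit")
    if abs(reference.exponent - GEOMETRIC_EXPONENT) > 1e-12:
        raise StateError(
            "reference exponent must be pinned at 2/3; "
            "build it with geometric_reference()"
        )
    if not S > 0 or not E > 0:
        raise DomainError("surface and volume must be positive")
    return S / (reference.coefficient * E ** GEOMETRIC_EXPONENT)
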