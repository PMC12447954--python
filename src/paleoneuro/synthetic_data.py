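"""Synthetic specimen tables with the statistical structure the analyses assume.

The generator emulates three features of real endocast tables so that every
estimator in the package can be exercised against known truth:

- power-law brain-body structure: log10 E = log10 b + alpha * log10 P plus
  lognormal residuals (Gaussian in log space, sd ``sd_log10E``);
- a neocorticalization trend: %NC either linear in geologic age or a
  saturating (Michaelis-Menten-shaped) function of the record's true EQ,
  clamped to (0, 100];
- within-species lognormal variation with an exact target CV.

Defaults mirror the packaged mammal table: reference allometry b = 0.12,
alpha = 2/3; body masses 100 g - 1000 kg; residual sd 0.1 in log10 ml
(about a factor 1.26 scatter); %NC rising 0.7 points/Myr from 16% at
-60 Ma to 58% today; within-species CV 10% over 8 specimens.

Everything is deterministic under (config, seed): identical configs write
byte-identical CSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataset import Section, SpecimenRecord
from .errors import ConfigError

#: Printed maxima of the living-reptile brain-body envelope, (P g, E g):
#: an American crocodile and an American alligator.
CROCODILE_MAXIMUM = (134_000.0, 15.6)
ALLIGATOR_MAXIMUM = (205_000.0, 14.08)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic specimen-table generator."""

    n_species: int = 200
    alpha_true: float = 2.0 / 3.0
    log10_b_true: float = math.log10(0.12)
    log10P_range: tuple[float, float] = (2.0, 6.0)
    sd_log10E: float = 0.1
    nc_model: str = "linear"  # "linear" (in age) or "saturating" (in EQ)
    nc_intercept: float = 58.0  # % at age 0 (linear model)
    nc_slope: float = 0.7  # % points per Myr (linear model)
    nc_max: float = 80.0  # plateau % (saturating model)
    nc_half_saturation: float = 0.5  # EQ at half the plateau (saturating)
    age_range_Ma: tuple[float, float] = (-60.0, 0.0)
    within_species_cv: float = 0.10
    n_within: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species", f"must be >= 1, got {self.n_species}")
        if self.log10P_range[0] >= self.log10P_range[1]:
            raise ConfigError("log10P_range", f"must be ordered, got {self.log10P_range}")
        if self.sd_log10E < 0:
            raise ConfigError("sd_log10E", f"must be >= 0, got {self.sd_log10E}")
        if self.nc_model not in ("linear", "saturating"):
            raise ConfigError("nc_model", f"must be 'linear' or 'saturating', got {self.nc_model!r}")
        if not self.nc_half_saturation > 0:
            raise ConfigError("nc_half_saturation", "must be positive")
        if not 0 < self.nc_max <= 100:
            raise ConfigError("nc_max", f"must be in (0, 100], got {self.nc_max}")
        if self.age_range_Ma[0] > self.age_range_Ma[1] or self.age_range_Ma[1] > 0:
            raise ConfigError("age_range_Ma", f"must be ordered with max <= 0, got {self.age_range_Ma}")
        if self.within_species_cv < 0:
            raise ConfigError("within_species_cv", f"must be >= 0, got {self.within_species_cv}")
        if self.n_within < 2:
            raise ConfigError("n_within", f"must be >= 2, got {self.n_within}")


def generate_dataset(config: SyntheticConfig) -> list[SpecimenRecord]:
    """Draw one synthetic specimen per species under the configured truths.

    Surface areas are back-filled consistently: total-minus-bulb surface
    follows a plausible cortical scaling S-OB = 3.75 * E**0.91, neocortex is
    the configured percentage of it, bulbs are 5% of it, and S is their
    exact sum, so every generated record passes dataset validation. The
    reported %NC and EQ columns carry the recomputable values rounded to 2
    decimals, as a printed table would.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_species

    log10P = rng.uniform(*config.log10P_range, size=n)
    resid = rng.normal(0.0, config.sd_log10E, size=n) if config.sd_log10E > 0 else np.zeros(n)
    log10E = config.log10_b_true + config.alpha_true * log10P + resid
    age = rng.uniform(config.age_range_Ma[0], config.age_range_Ma[1], size=n)

    P = 10.0 ** log10P
    E = 10.0 ** log10E
    true_eq = 10.0 ** resid  # E relative to the generating reference line

    if config.nc_model == "linear":
        pct = config.nc_intercept + config.nc_slope * age
    else:
        pct = config.nc_max * true_eq / (config.nc_half_saturation + true_eq)
    pct = np.clip(pct, 1e-6, 100.0)

    s_minus_ob = 3.75 * E ** 0.91
    nc = pct / 100.0 * s_minus_ob
    ob = 0.05 * s_minus_ob
    s = ob + s_minus_ob
    b_ref = 10.0 ** config.log10_b_true
    eq_col = E / (b_ref * P ** config.alpha_true)

    records = []
    for i in range(n):
        records.append(SpecimenRecord(
            species=f"Synthspecies {i:04d}",
            specimen_id=f"SYN {config.seed}-{i:04d}",
            section=Section.FOSSIL if age[i] < 0 else Section.LIVING_NONPRIMATE,
            taxon="Synthetica",
            S=float(s[i]),
            OB=float(ob[i]),
            S_minus_OB=float(s_minus_ob[i]),
            NC=float(nc[i]),
            age_Ma=float(age[i]),
            E=float(E[i]),
            P=float(P[i]),
            pctNC_reported=round(float(pct[i]), 2),
            EQ_reported=round(float(eq_col[i]), 2),
        ))
    return records


def generate_within_species(
    mean_E: float, cv: float, n: int, seed: int
) -> list[float]:
    """Lognormal volume draws whose distribution has exactly the target CV.

    For a lognormal, CV = sqrt(exp(sigma^2) - 1), so sigma is chosen as
    sqrt(log(1 + cv^2)) and mu so the distribution mean equals ``mean_E``.
    ``cv = 0`` degenerates to n identical values.
    """
    if not mean_E > 0:
        raise ConfigError("mean_E", f"must be positive, got {mean_E}")
    if cv < 0:
        raise ConfigError("cv", f"must be >= 0, got {cv}")
    if n < 2:
        raise ConfigError("n", f"must be >= 2, got {n}")
    if cv == 0:
        return [float(mean_E)] * n
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = math.log(mean_E) - 0.5 * sigma * sigma
    rng = np.random.default_rng(seed)
    return [float(v) for v in rng.lognormal(mu, sigma, size=n)]


def reptile_brain_body_points(
    n: int = 59, seed: int = 0, sd_log10E: float = 0.12
) -> list[tuple[float, float]]:
    """A synthetic stand-in for the living-reptile brain-body cloud.

    The published reptile polygon's underlying 59 (body mass, brain mass)
    points are not printed; only the two crocodilian maxima are. This
    generates a reptile-grade cloud — intercept b = 0.005 g/g^(2/3)
    (classical reptile-level encephalization), theoretical 2/3 slope,
    Gaussian log residuals — spanning 10 g up to the printed alligator
    maximum, and appends the two printed anchor points so the polygon's
    upper-right boundary is pinned by real published values.
    """
    rng = np.random.default_rng(seed)
    log10P = rng.uniform(1.0, math.log10(ALLIGATOR_MAXIMUM[0]), size=n - 2)
    log10E = math.log10(0.005) + (2.0 / 3.0) * log10P + rng.normal(0.0, sd_log10E, size=n - 2)
    pts = [(float(10 ** p), float(10 ** e)) for p, e in zip(log10P, log10E)]
    return pts + [CROCODILE_MAXIMUM, ALLIGATOR_MAXIMUM]
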