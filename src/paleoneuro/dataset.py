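"""Specimen data model, table IO, and consistency validation.

The central container is :class:`SpecimenRecord`, one row per endocast or
brain with surface areas (cm^2), endocast length (cm), geologic age (Ma,
negative = past), endocranial volume (ml) and body mass (g) in the cgs
convention. Two verbatim measurement tables are packaged as fixtures:

``table1_mammals``
    158 mammal specimens (117 fossil, 22 living non-primates, 19 living
    primates) with surface areas, volumes, body masses and the published
    neocorticalization (%NC) and encephalization-quotient (EQ) columns.
``table2_bathygenys``
    8 *Bathygenys reevesi* endocasts (volume, surface area, neocortex area
    and neocortex:surface ratio) used for within-species variation.

Loading never drops or mutates rows; derived-column consistency is checked
separately by :func:`validate_records`, which reports failures instead of
raising, so known-inconsistent printed cells (e.g. the *Equus occidentalis*
%NC cell) stay visible in the data.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, fields, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import DomainError, SchemaError, TableParseError

logger = logging.getLogger(__name__)

#: Canonical column order of the measurement-table CSV schema.
COLUMNS = [
    "species", "specimen_id", "section", "taxon",
    "S_cm2", "OB_cm2", "S_minus_OB_cm2", "NC_cm2", "L_cm",
    "age_Ma", "E_ml", "P_g", "pctNC", "EQ",
]

#: Column schema of the within-species (Bathygenys) fixture.
TABLE2_COLUMNS = ["specimen_id", "E_ml", "S_cm2", "nc_cm2", "nc_over_S"]

_NUMERIC = {
    "S_cm2": "S", "OB_cm2": "OB", "S_minus_OB_cm2": "S_minus_OB",
    "NC_cm2": "NC", "L_cm": "L", "age_Ma": "age_Ma", "E_ml": "E",
    "P_g": "P", "pctNC": "pctNC_reported", "EQ": "EQ_reported",
}


class Section(str, Enum):
    """Which block of the measurement table a specimen belongs to."""

    FOSSIL = "fossil"
    LIVING_NONPRIMATE = "living_nonprimate"
    LIVING_PRIMATE = "living_primate"


@dataclass(frozen=True)
class SpecimenRecord:
    """One endocast or brain: areas, length, age, volume, body mass.

    All linear measures follow the cgs convention (cm^2, cm, ml, g).
    ``None`` means the printed cell was blank; ``OB == 0`` is distinct from
    ``OB is None`` and means the olfactory bulbs were absent from the cast.
    ``age_Ma`` is <= 0 after loader normalization (0 = extant).
    """

    species: str
    specimen_id: str
    section: Section
    taxon: str
    S: float | None = None
    OB: float | None = None
    S_minus_OB: float | None = None
    NC: float | None = None
    L: float | None = None
    age_Ma: float | None = None
    E: float | None = None
    P: float | None = None
    pctNC_reported: float | None = None
    EQ_reported: float | None = None

    @property
    def label(self) -> str:
        return f"{self.species} {self.specimen_id}".strip()


@dataclass(frozen=True)
class CheckResult:
    check_name: str
    status: str  # "pass" | "fail" | "skipped_missing"
    detail: str = ""
    recomputed_value: float | None = None


@dataclass(frozen=True)
class ValidationReport:
    """All consistency checks for one record; failures never abort loading."""

    record_index: int
    record_label: str
    checks: tuple[CheckResult, ...]

    @property
    def failed(self) -> bool:
        return any(c.status == "fail" for c in self.checks)


def fixture_path(name: str) -> Path:
    """Return the filesystem path of a packaged fixture CSV."""
    if not name.endswith(".csv"):
        name += ".csv"
    path = resources.files("paleoneuro.data") / name
    return Path(str(path))


def _parse_cell(raw: str, column: str, row: int) -> float | None:
    raw = raw.strip().replace(",", "")  # strip thousands separators
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise TableParseError(
            f"non-numeric value {raw!r} in column {column!r}, data row {row}",
            row=row, column=column,
        ) from None


def load_table(
    path_or_fixture_name: str | Path,
    section_map: Mapping[str, str] | None = None,
) -> list[SpecimenRecord]:
    """Read a comma-separated measurement table into records, in file order.

    ``path_or_fixture_name`` is either a filesystem path or the name of a
    packaged fixture (``"table1_mammals"``, ``"table2_bathygenys"``). Blank
    cells become ``None``; no row is ever dropped. ``section_map`` optionally
    remaps raw section-column values onto the canonical section names.

    Positive geologic ages on fossil-section rows (the table prints a
    handful, all recent La Brea material plus one typo) are normalized to
    negative, with each normalization logged.
    """
    path = Path(path_or_fixture_name)
    if not path.exists():
        path = fixture_path(str(path_or_fixture_name))
        if not path.exists():
            raise FileNotFoundError(f"no such table or fixture: {path_or_fixture_name}")

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: no header row") from None
        header = [h.strip() for h in header]
        if header == TABLE2_COLUMNS:
            return _load_table2_rows(reader)
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"header is missing required column(s): {missing}")
        idx = {c: header.index(c) for c in COLUMNS}

        records: list[SpecimenRecord] = []
        for i, row in enumerate(reader, start=1):
            section_raw = row[idx["section"]].strip()
            if section_map and section_raw in section_map:
                section_raw = section_map[section_raw]
            try:
                section = Section(section_raw)
            except ValueError:
                raise TableParseError(
                    f"unknown section {section_raw!r} in data row {i}",
                    row=i, column="section",
                ) from None
            values = {
                field: _parse_cell(row[idx[col]], col, i)
                for col, field in _NUMERIC.items()
            }
            rec = SpecimenRecord(
                species=row[idx["species"]].strip(),
                specimen_id=row[idx["specimen_id"]].strip(),
                section=section,
                taxon=row[idx["taxon"]].strip(),
                **values,
            )
            if (
                rec.section is Section.FOSSIL
                and rec.age_Ma is not None
                and rec.age_Ma > 0
            ):
                logger.info(
                    "normalizing positive fossil age %+g Ma -> %g Ma for %s",
                    rec.age_Ma, -rec.age_Ma, rec.label,
                )
                rec = replace(rec, age_Ma=-rec.age_Ma)
            records.append(rec)
    return records


def _load_table2_rows(reader: Iterable[list[str]]) -> list[SpecimenRecord]:
    records = []
    for i, row in enumerate(reader, start=1):
        records.append(
            SpecimenRecord(
                species="Bathygenys reevesi",
                specimen_id=row[0].strip(),
                section=Section.FOSSIL,
                taxon="Artiodactyla",
                E=_parse_cell(row[1], "E_ml", i),
                S=_parse_cell(row[2], "S_cm2", i),
                NC=_parse_cell(row[3], "nc_cm2", i),
            )
        )
    return records


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return format(value, "g") if value == int(value) else repr(value)


def write_table(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    """Write records back to CSV in the canonical schema (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.species, rec.specimen_id, rec.section.value, rec.taxon]
                + [_fmt(getattr(rec, _NUMERIC[c])) for c in COLUMNS[4:]]
            )


def validate_records(
    records: Sequence[SpecimenRecord],
    tolerance_pct: float = 0.05,
    eq_tolerance: float = 0.01,
    additivity_tolerance: float = 0.05,
) -> list[ValidationReport]:
    """Recompute derived columns and flag rows whose printed cells disagree.

    Three checks per record, each ``pass``/``fail``/``skipped_missing``:

    - ``pctNC``: 100*NC/(S-OB) within ``tolerance_pct`` points of the
      printed %NC column;
    - ``EQ``: E/(0.12*P^(2/3)), rounded to 2 decimals, within
      ``eq_tolerance`` of the printed EQ column;
    - ``additivity``: |S - OB - (S-OB column)| <= ``additivity_tolerance``
      cm^2 (rows whose casts lack bulbs can legitimately fail this).

    Failures are reported, never raised, and records are never mutated.
    """
    from . import allometry

    eps = 1e-9
    reports = []
    for i, rec in enumerate(records):
        checks: list[CheckResult] = []

        if rec.NC is None or rec.S_minus_OB is None or rec.pctNC_reported is None:
            checks.append(CheckResult("pctNC", "skipped_missing"))
        else:
            recomputed = 100.0 * rec.NC / rec.S_minus_OB
            ok = abs(recomputed - rec.pctNC_reported) <= tolerance_pct + eps
            checks.append(CheckResult(
                "pctNC", "pass" if ok else "fail",
                f"recomputed {recomputed:.2f} vs printed {rec.pctNC_reported}",
                recomputed_value=recomputed,
            ))

        if rec.E is None or rec.P is None or rec.EQ_reported is None:
            checks.append(CheckResult("EQ", "skipped_missing"))
        else:
            recomputed = round(allometry.eq(rec.E, rec.P).eq, 2)
            ok = abs(recomputed - rec.EQ_reported) <= eq_tolerance + eps
            checks.append(CheckResult(
                "EQ", "pass" if ok else "fail",
                f"recomputed {recomputed:.2f} vs printed {rec.EQ_reported}",
                recomputed_value=recomputed,
            ))

        if rec.S is None or rec.OB is None or rec.S_minus_OB is None:
            checks.append(CheckResult("additivity", "skipped_missing"))
        else:
            resid = rec.S - rec.OB - rec.S_minus_OB
            ok = abs(resid) <= additivity_tolerance + eps
            checks.append(CheckResult(
                "additivity", "pass" if ok else "fail",
                f"S - OB - (S-OB) = {resid:.2f} cm^2",
                recomputed_value=resid,
            ))

        reports.append(ValidationReport(i, rec.label, tuple(checks)))
    return reports


def require_fields(
    records: Sequence[SpecimenRecord], *field_names: str
) -> tuple[list[SpecimenRecord], int]:
    """Keep records where every named field is present; report the drop count.

    Downstream stages declare the fields they need through this helper so the
    missing-cell policy is uniform and observable (the drop count is logged).
    """
    valid = {f.name for f in fields(SpecimenRecord)}
    for name in field_names:
        if name not in valid:
            raise DomainError(f"unknown SpecimenRecord field: {name!r}")
    kept = [
        r for r in records
        if all(getattr(r, name) is not None for name in field_names)
    ]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info(
            "dropped %d of %d records missing %s", dropped, len(records),
            ", ".join(field_names),
        )
    return kept, dropped
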