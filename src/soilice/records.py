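"""Toxicity-record data model, CSV ingestion, and unit normalization.

A :class:`ToxicityRecord` is one measured endpoint (an LC50 or a mortality
LOEC) for one species x chemical x exposure-duration combination, with the
concentration in a declared unit.  Records are read from a flat CSV schema
emulating exports from the ECOTOX and Standartox knowledgebases; ingestion
always starts from a local file, never a web service.

Concentrations are expressed on a soil dry-mass basis.  The supported unit
dialect covers the common soil-toxicity spellings (mg/kg, g/kg, ug/g, ng/g,
ug/kg, ppm, ppb); aqueous units such as mg/L are refused because they are
not convertible to a soil mass basis without exposure-media assumptions.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Union

import pandas as pd

from .errors import SchemaError, UnitConversionError

logger = logging.getLogger(__name__)

#: Exact CSV column names, in file order.
CSV_COLUMNS = [
    "species_latin",
    "common_name",
    "taxon_group",
    "phylum",
    "class",
    "order",
    "chemical_id",
    "chemical_name",
    "endpoint_type",
    "effect",
    "duration_days",
    "concentration",
    "unit",
    "source_id",
]

ENDPOINT_TYPES = frozenset({"LC50", "LOEC"})
EFFECTS = frozenset({"mortality"})
TAXON_GROUPS = frozenset(
    {"earthworm", "springtail", "nematode", "potworm", "woodlouse", "other"}
)

# Multiplicative factors to mg/kg dry soil.  "ppm" is read as mg/kg dry soil,
# the convention of the soil-toxicity literature.  Both the micro sign and the
# ASCII "u" spelling are accepted.
UNIT_FACTORS = {
    "mg/kg": 1.0,
    "g/kg": 1000.0,
    "ug/g": 1.0,
    "µg/g": 1.0,
    "μg/g": 1.0,
    "ng/g": 1e-3,
    "ug/kg": 1e-3,
    "µg/kg": 1e-3,
    "μg/kg": 1e-3,
    "ppm": 1.0,
    "ppb": 1e-3,
}

# One accepted binomial per species; keys are lower-cased, whitespace-collapsed.
# The toxicology literature itself is not consistent in spelling (e.g. the
# African nightcrawler appears as both "Eudrilus eugeniae" and
# "Eudrilus euganiae"), so variants are folded onto a single canonical name.
SPECIES_SPELLING_VARIANTS = {
    "eudrilus euganiae": "Eudrilus eugeniae",
}

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def canonical_species(name: str) -> str:
    """Canonicalize a Latin binomial: collapse whitespace, fix case, and fold
    known spelling variants onto one accepted binomial."""
    key = " ".join(str(name).split()).lower()
    if key in SPECIES_SPELLING_VARIANTS:
        return SPECIES_SPELLING_VARIANTS[key]
    if not key:
        return ""
    parts = key.split(" ")
    return " ".join([parts[0].capitalize()] + parts[1:])


def normalize_chemical_id(raw: str) -> str:
    """Normalize a chemical identifier to a stable matching key.

    A CAS registry number (with or without hyphens/spaces) is returned in its
    canonical hyphenated form; anything else is treated as a free-text name
    and lower-cased with whitespace collapsed.  The operation is idempotent.
    """
    s = " ".join(str(raw).split())
    compact = s.replace("-", "").replace(" ", "")
    if compact.isdigit() and 5 <= len(compact) <= 10:
        return f"{compact[:-3]}-{compact[-3:-1]}-{compact[-1]}"
    if _CAS_RE.match(s):
        return s
    return s.lower()


@dataclass(frozen=True)
class ToxicityRecord:
    """One measured toxicity endpoint for a species x chemical x duration.

    ``concentration`` is interpreted in ``unit``; call
    :func:`normalize_records` to bring a record list onto the mg/kg scale.
    """

    species_latin: str
    common_name: str
    taxon_group: str
    phylum: str
    class_: str
    order: str
    chemical_id: str
    chemical_name: str
    endpoint_type: str
    effect: str
    duration_days: float
    concentration: float
    unit: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"concentration must be positive, got {self.concentration}")
        if self.duration_days <= 0:
            raise ValueError(f"duration_days must be positive, got {self.duration_days}")
        if self.endpoint_type not in ENDPOINT_TYPES:
            raise ValueError(f"endpoint_type must be one of {sorted(ENDPOINT_TYPES)}")
        if self.effect not in EFFECTS:
            raise ValueError(f"effect must be one of {sorted(EFFECTS)}")
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"taxon_group must be one of {sorted(TAXON_GROUPS)}")
        object.__setattr__(self, "species_latin", canonical_species(self.species_latin))
        object.__setattr__(self, "chemical_id", normalize_chemical_id(self.chemical_id))


@dataclass
class ParseReport:
    """Row accounting for one parse: accepted + rejected = data rows seen."""

    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def normalize_concentration(value: float, unit: str) -> float:
    """Convert ``value`` in ``unit`` to mg/kg dry soil.

    Raises :class:`UnitConversionError` for units outside the supported soil
    dialect (notably any aqueous unit).
    """
    if value <= 0:
        raise ValueError(f"concentration must be positive, got {value}")
    key = str(unit).strip()
    try:
        factor = UNIT_FACTORS[key]
    except KeyError:
        raise UnitConversionError(f"unsupported unit: {unit!r}") from None
    return value * factor


def _coerce_row(idx: int, row: pd.Series) -> ToxicityRecord:
    try:
        conc = float(row["concentration"])
    except (TypeError, ValueError):
        raise ValueError("non-numeric concentration") from None
    try:
        dur = float(row["duration_days"])
    except (TypeError, ValueError):
        raise ValueError("non-numeric duration_days") from None
    return ToxicityRecord(
        species_latin=str(row["species_latin"]),
        common_name=str(row.get("common_name", "") or ""),
        taxon_group=str(row["taxon_group"]).strip().lower(),
        phylum=str(row.get("phylum", "") or ""),
        class_=str(row.get("class", "") or ""),
        order=str(row.get("order", "") or ""),
        chemical_id=str(row["chemical_id"]),
        chemical_name=str(row.get("chemical_name", "") or ""),
        endpoint_type=str(row["endpoint_type"]).strip(),
        effect=str(row["effect"]).strip().lower(),
        duration_days=dur,
        concentration=conc,
        unit=str(row["unit"]).strip(),
        source_id=str(row.get("source_id", "") or ""),
    )


def parse_records(
    source: Union[str, Path, IO[str]],
) -> tuple[list[ToxicityRecord], ParseReport]:
    """Parse the record CSV schema into :class:`ToxicityRecord` objects.

    Well-formed rows become records in file order; malformed rows are
    rejected individually (never a crash) and logged, with the reason kept in
    the returned :class:`ParseReport`.  A missing mandatory column raises
    :class:`SchemaError` naming the column.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False, encoding="utf-8")
    mandatory = [
        "species_latin", "taxon_group", "chemical_id",
        "endpoint_type", "effect", "duration_days", "concentration", "unit",
    ]
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col!r}")

    records: list[ToxicityRecord] = []
    report = ParseReport(n_rows=len(df))
    for idx, row in df.iterrows():
        try:
            records.append(_coerce_row(int(idx), row))
            report.n_accepted += 1
        except ValueError as exc:
            report.rejected.append((int(idx), str(exc)))
            logger.warning("rejected row %d: %s", idx, exc)
    return records, report


def normalize_records(
    records: Iterable[ToxicityRecord],
) -> tuple[list[ToxicityRecord], list[tuple[ToxicityRecord, str]]]:
    """Convert every record to mg/kg.  Records in unsupported units are
    excluded (the convertibility filter) and returned separately with the
    offending unit named."""
    kept: list[ToxicityRecord] = []
    dropped: list[tuple[ToxicityRecord, str]] = []
    for rec in records:
        try:
            conc = normalize_concentration(rec.concentration, rec.unit)
        except UnitConversionError as exc:
            dropped.append((rec, str(exc)))
            logger.warning("excluded record (%s %s): %s", rec.species_latin, rec.chemical_id, exc)
            continue
        kept.append(replace(rec, concentration=conc, unit="mg/kg"))
    return kept, dropped


def records_to_frame(records: Iterable[ToxicityRecord]) -> pd.DataFrame:
    rows = [
        {
            "species_latin": r.species_latin,
            "common_name": r.common_name,
            "taxon_group": r.taxon_group,
            "phylum": r.phylum,
            "class": r.class_,
            "order": r.order,
            "chemical_id": r.chemical_id,
            "chemical_name": r.chemical_name,
            "endpoint_type": r.endpoint_type,
            "effect": r.effect,
            "duration_days": r.duration_days,
            "concentration": r.concentration,
            "unit": r.unit,
            "source_id": r.source_id,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_records(records: Iterable[ToxicityRecord], dest: Union[str, Path, IO[str]]) -> None:
    """Write records in the canonical CSV schema (UTF-8, '.' decimals)."""
    frame = records_to_frame(records)
    if isinstance(dest, (str, Path)):
        frame.to_csv(dest, index=False, encoding="utf-8")
    else:
        frame.to_csv(dest, index=False)


def records_to_csv_string(records: Iterable[ToxicityRecord]) -> str:
    buf = io.StringIO()
    write_records(records, buf)
    return buf.getvalue()
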