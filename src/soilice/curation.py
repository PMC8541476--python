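"""Curation filters and species mean acute values (SMAVs).

The curation stage keeps only records from standard acute soil toxicity test
durations (1 day for nematodes such as *Caenorhabditis elegans*, 14 days for
earthworms and springtails), with the configured endpoint types and effects,
and drops any species with data for fewer than a minimum number of distinct
chemicals per endpoint.  Surviving records are collapsed to one SMAV — the
geometric mean of qualifying values — per species x chemical x endpoint.

Life stages are pooled and no soil-property standardization (pH, organic
matter, clay) is attempted; the data are used as reported.  LC50 and LOEC
streams never mix from the SMAV stage onward.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import CurationError
from .records import ToxicityRecord

#: Standard acute test duration (days) per taxon group.  Potworm and
#: woodlouse durations are not standardized in the source literature; 14 d
#: is the configurable default.
DEFAULT_DURATION_RULE: dict[str, float] = {
    "nematode": 1.0,
    "earthworm": 14.0,
    "springtail": 14.0,
    "potworm": 14.0,
    "woodlouse": 14.0,
    "other": 14.0,
}


@dataclass
class CurationConfig:
    """Parameters of the curation stage.

    duration_rule
        Required exposure duration, in days, per taxon group.  Matching is
        exact (no window); non-standard durations such as 2-day contact
        tests are excluded.
    min_chemicals_per_species
        A species must have data for at least this many distinct chemicals
        (per endpoint type) to be retained.
    """

    duration_rule: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_RULE)
    )
    min_chemicals_per_species: int = 3
    allowed_endpoints: frozenset[str] = frozenset({"LC50", "LOEC"})
    allowed_effects: frozenset[str] = frozenset({"mortality"})

    def __post_init__(self) -> None:
        if self.min_chemicals_per_species < 1:
            raise ValueError("min_chemicals_per_species must be >= 1")
        for group, days in self.duration_rule.items():
            if days <= 0:
                raise ValueError(f"duration for {group!r} must be positive")
        self.allowed_endpoints = frozenset(self.allowed_endpoints)
        self.allowed_effects = frozenset(self.allowed_effects)

    def to_dict(self) -> dict:
        return {
            "duration_rule": dict(self.duration_rule),
            "min_chemicals_per_species": self.min_chemicals_per_species,
            "allowed_endpoints": sorted(self.allowed_endpoints),
            "allowed_effects": sorted(self.allowed_effects),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CurationConfig":
        kwargs = {}
        if "duration_rule" in data:
            kwargs["duration_rule"] = {k: float(v) for k, v in data["duration_rule"].items()}
        if "min_chemicals_per_species" in data:
            kwargs["min_chemicals_per_species"] = int(data["min_chemicals_per_species"])
        if "allowed_endpoints" in data:
            kwargs["allowed_endpoints"] = frozenset(data["allowed_endpoints"])
        if "allowed_effects" in data:
            kwargs["allowed_effects"] = frozenset(data["allowed_effects"])
        return cls(**kwargs)


@dataclass(frozen=True)
class SMAV:
    """Species mean acute value: geometric mean of qualifying toxicity values
    for one species x chemical x endpoint type, in mg/kg."""

    species_latin: str
    chemical_id: str
    endpoint_type: str
    value: float
    n_records: int

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("SMAV value must be positive")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")


def filter_acute(
    records: Iterable[ToxicityRecord], config: CurationConfig
) -> list[ToxicityRecord]:
    """Keep records at the standard acute duration for their taxon group with
    an allowed endpoint type and effect."""
    kept = []
    for rec in records:
        if rec.taxon_group not in config.duration_rule:
            raise CurationError(
                f"no duration rule configured for taxon group {rec.taxon_group!r}"
            )
        if rec.endpoint_type not in config.allowed_endpoints:
            continue
        if rec.effect not in config.allowed_effects:
            continue
        if rec.duration_days != config.duration_rule[rec.taxon_group]:
            continue
        kept.append(rec)
    return kept


def filter_min_chemicals(records: Iterable[ToxicityRecord], k: int) -> list[ToxicityRecord]:
    """Drop all records of any species with fewer than ``k`` distinct
    chemicals for a given endpoint type."""
    if k < 1:
        raise ValueError("k must be >= 1")
    records = list(records)
    chems: dict[tuple[str, str], set[str]] = defaultdict(set)
    for rec in records:
        chems[(rec.species_latin, rec.endpoint_type)].add(rec.chemical_id)
    return [
        rec for rec in records
        if len(chems[(rec.species_latin, rec.endpoint_type)]) >= k
    ]


def compute_smavs(records: Iterable[ToxicityRecord]) -> list[SMAV]:
    """One geometric-mean SMAV per (species, chemical, endpoint) group.

    All input records must already be on the mg/kg scale.
    """
    groups: dict[tuple[str, str, str], list[float]] = defaultdict(list)
    for rec in records:
        groups[(rec.species_latin, rec.chemical_id, rec.endpoint_type)].append(
            rec.concentration
        )
    out = []
    for (species, chem, endpoint), values in sorted(groups.items()):
        gm = math.exp(sum(math.log(v) for v in values) / len(values))
        out.append(SMAV(species, chem, endpoint, gm, len(values)))
    return out


def curate(
    records: Iterable[ToxicityRecord], config: CurationConfig | None = None
) -> list[SMAV]:
    """Full curation: acute/endpoint filter, then min-chemicals filter
    (counted on acute-qualifying data), then SMAVs.  The filter order is
    fixed."""
    config = config or CurationConfig()
    acute = filter_acute(records, config)
    retained = filter_min_chemicals(acute, config.min_chemicals_per_species)
    return compute_smavs(retained)


def smavs_to_frame(smavs: Iterable[SMAV]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_latin": s.species_latin,
                "chemical_id": s.chemical_id,
                "endpoint_type": s.endpoint_type,
                "smav_mg_per_kg": s.value,
                "n_records": s.n_records,
            }
            for s in smavs
        ],
        columns=["species_latin", "chemical_id", "endpoint_type", "smav_mg_per_kg", "n_records"],
    )
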