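"""Synthetic soil-toxicity databases with known interspecies structure.

The generator emulates the statistical structure the ICE regression assumes:
every chemical c carries a latent log10 potency x_c drawn from
Normal(mu, tau^2), and each species s responds with a true log10 SMAV

    y_sc = alpha_s + beta_s * x_c + e_sc,   e_sc ~ Normal(0, sigma_s^2)

so two species A and B are linearly related on the log scale with true slope
beta_B / beta_A.  Because noise sits on *both* species (as in real data),
the OLS slope of B on A's observed values is attenuated toward zero:

    E[slope] ~= beta_A * beta_B * tau^2 / (beta_A^2 * tau^2 + sigma_A^2)

and parameter-recovery checks must target this attenuated value, not the
naive beta ratio.  Each species covers a configurable fraction of the
chemicals (independent thinning), each covered cell emits one or more
replicate records with multiplicative lognormal noise, and records are
emitted in a configurable mix of concentration units with durations chosen
so the default curation retains them.  All randomness flows from a single
seeded generator; identical (config, seed) gives byte-identical tables.

The generator makes no attempt to mimic real chemical classes, modes of
action, or soil-property effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .curation import DEFAULT_DURATION_RULE
from .records import UNIT_FACTORS, ToxicityRecord, write_records

#: Default taxonomy annotation per taxon group.
TAXON_TAXONOMY: dict[str, tuple[str, str, str]] = {
    "earthworm": ("Annelida", "Clitellata", "Opisthopora"),
    "potworm": ("Annelida", "Clitellata", "Enchytraeida"),
    "springtail": ("Arthropoda", "Collembola", "Entomobryomorpha"),
    "woodlouse": ("Arthropoda", "Malacostraca", "Isopoda"),
    "nematode": ("Nematoda", "Chromadorea", "Rhabditida"),
    "other": ("", "", ""),
}


@dataclass(frozen=True)
class SpeciesProfile:
    """Ground-truth sensitivity profile of one synthetic species.

    alpha/beta place the species' log10 SMAV linearly in the shared latent
    potency; sigma is the species-level residual sd (log10 units); coverage
    is the fraction of chemicals with any data for this species.
    """

    name: str
    taxon_group: str
    alpha: float
    beta: float
    sigma: float
    coverage: float = 1.0
    replicates_per_cell: int = 1
    replicate_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError("coverage must be in (0, 1]")
        if self.sigma < 0 or self.replicate_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        if self.taxon_group not in TAXON_TAXONOMY:
            raise ValueError(f"unknown taxon_group {self.taxon_group!r}")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic database.

    Defaults describe a moderately noisy two-earthworm study on a realistic
    potency scale: chemical potencies centred at 100 mg/kg (mu = 2 on the
    log10 scale) spanning roughly two orders of magnitude (tau = 1), with
    species residual sd 0.2 log10 units — about the replicate variability of
    acute soil assays.
    """

    n_chemicals: int
    seed: int
    potency_mean: float = 2.0
    potency_sd: float = 1.0
    species: tuple[SpeciesProfile, ...] = (
        SpeciesProfile("Eisenia fetida", "earthworm", alpha=0.0, beta=1.0, sigma=0.2),
        SpeciesProfile("Eisenia andrei", "earthworm", alpha=0.3, beta=0.9, sigma=0.2),
    )
    endpoint_type: str = "LC50"
    duration_rule: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_RULE)
    )
    unit_mix: dict[str, float] = field(default_factory=lambda: {"mg/kg": 1.0})

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be >= 1")
        if self.potency_sd < 0:
            raise ValueError("potency_sd must be >= 0")
        self.species = tuple(self.species)
        for unit in self.unit_mix:
            if unit not in UNIT_FACTORS:
                raise ValueError(f"unit_mix contains unsupported unit {unit!r}")
        total = sum(self.unit_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("unit_mix probabilities must sum to 1")

    def to_dict(self) -> dict:
        return {
            "n_chemicals": self.n_chemicals,
            "seed": self.seed,
            "potency_mean": self.potency_mean,
            "potency_sd": self.potency_sd,
            "endpoint_type": self.endpoint_type,
            "duration_rule": dict(self.duration_rule),
            "unit_mix": dict(self.unit_mix),
            "species": [
                {
                    "name": s.name,
                    "taxon_group": s.taxon_group,
                    "alpha": s.alpha,
                    "beta": s.beta,
                    "sigma": s.sigma,
                    "coverage": s.coverage,
                    "replicates_per_cell": s.replicates_per_cell,
                    "replicate_sd": s.replicate_sd,
                }
                for s in self.species
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        species = tuple(SpeciesProfile(**sp) for sp in data.get("species", []))
        kwargs = {k: data[k] for k in
                  ("n_chemicals", "seed", "potency_mean", "potency_sd",
                   "endpoint_type") if k in data}
        if species:
            kwargs["species"] = species
        if "duration_rule" in data:
            kwargs["duration_rule"] = {k: float(v) for k, v in data["duration_rule"].items()}
        if "unit_mix" in data:
            kwargs["unit_mix"] = dict(data["unit_mix"])
        return cls(**kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Latent quantities behind one generated table, for recovery checks."""

    potencies: dict[str, float]
    species: tuple[SpeciesProfile, ...]

    def profile(self, name: str) -> SpeciesProfile:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def true_slope(self, surrogate: str, predicted: str) -> float:
        """Slope of the noiseless log-log relation, beta_pred / beta_surr."""
        return self.profile(predicted).beta / self.profile(surrogate).beta

    def attenuated_slope(self, surrogate: str, predicted: str, tau: float) -> float:
        """Expected OLS slope given noise on the surrogate axis."""
        s, p = self.profile(surrogate), self.profile(predicted)
        return s.beta * p.beta * tau**2 / (s.beta**2 * tau**2 + s.sigma**2)

    def true_correlation(self, a: str, b: str, tau: float) -> float:
        sa, sb = self.profile(a), self.profile(b)
        cov = sa.beta * sb.beta * tau**2
        va = sa.beta**2 * tau**2 + sa.sigma**2
        vb = sb.beta**2 * tau**2 + sb.sigma**2
        return cov / np.sqrt(va * vb)


def generate_records(config: SyntheticConfig) -> tuple[list[ToxicityRecord], GroundTruth]:
    """Generate a record table and its ground truth, deterministically.

    Draw order is fixed (chemical potencies, then species in profile order,
    chemicals in index order) so identical (config, seed) reproduces the
    table bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_chemicals
    chem_ids = [f"chem-{i + 1:04d}" for i in range(n)]
    potencies = rng.normal(config.potency_mean, config.potency_sd, n)

    units = sorted(config.unit_mix)
    unit_p = np.array([config.unit_mix[u] for u in units])

    records: list[ToxicityRecord] = []
    for sp in config.species:
        phylum, class_, order = TAXON_TAXONOMY[sp.taxon_group]
        duration = config.duration_rule[sp.taxon_group]
        covered = rng.random(n) < sp.coverage
        cell_noise = rng.normal(0.0, 1.0, n) * sp.sigma
        for i in range(n):
            if not covered[i]:
                continue
            log_smav = sp.alpha + sp.beta * potencies[i] + cell_noise[i]
            for rep in range(sp.replicates_per_cell):
                log_conc = log_smav + (
                    rng.normal(0.0, 1.0) * sp.replicate_sd
                    if sp.replicate_sd > 0
                    else 0.0
                )
                unit = units[int(rng.choice(len(units), p=unit_p))] if len(units) > 1 else units[0]
                mg_per_kg = 10.0 ** log_conc
                records.append(
                    ToxicityRecord(
                        species_latin=sp.name,
                        common_name=sp.taxon_group,
                        taxon_group=sp.taxon_group,
                        phylum=phylum,
                        class_=class_,
                        order=order,
                        chemical_id=chem_ids[i],
                        chemical_name=chem_ids[i],
                        endpoint_type=config.endpoint_type,
                        effect="mortality",
                        duration_days=duration,
                        concentration=mg_per_kg / UNIT_FACTORS[unit],
                        unit=unit,
                        source_id=f"synthetic:seed={config.seed}",
                    )
                )
    truth = GroundTruth(
        potencies=dict(zip(chem_ids, potencies.tolist())), species=config.species
    )
    return records, truth


def _fixture_record(species, group, chem, endpoint, duration, conc, unit="mg/kg"):
    phylum, class_, order = TAXON_TAXONOMY[group]
    return ToxicityRecord(
        species_latin=species, common_name=group, taxon_group=group,
        phylum=phylum, class_=class_, order=order,
        chemical_id=chem, chemical_name=chem, endpoint_type=endpoint,
        effect="mortality", duration_days=duration, concentration=conc,
        unit=unit, source_id="fixture",
    )


def make_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write deterministic hand-built CSV fixtures covering the pipeline's
    boundary cases; returns {fixture name: path}.

    - ``minimal_pair``: two earthworm species sharing exactly 3 chemicals —
      the smallest model-eligible case (two directed models, too small for
      cross-validation).
    - ``loocv_pair``: two species sharing 4 chemicals, exactly collinear —
      the smallest cross-validation-eligible case.
    - ``unit_variety``: the same data expressed across the supported unit
      dialect.
    - ``subthreshold``: includes a species with only 2 chemicals, which the
      min-chemicals curation rule must drop.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    minimal = [
        _fixture_record("Eisenia fetida", "earthworm", c, "LC50", 14, v)
        for c, v in [("chem-a", 10.0), ("chem-b", 100.0), ("chem-c", 1000.0)]
    ] + [
        _fixture_record("Eisenia andrei", "earthworm", c, "LC50", 14, v)
        for c, v in [("chem-a", 20.0), ("chem-b", 150.0), ("chem-c", 2000.0)]
    ]
    paths["minimal_pair"] = out_dir / "minimal_pair.csv"
    write_records(minimal, paths["minimal_pair"])

    # y = x exactly: every hold-out refit is exact, success rate 100%.
    loocv_vals = [("chem-a", 1.0), ("chem-b", 10.0), ("chem-c", 100.0), ("chem-d", 1000.0)]
    loocv = [
        _fixture_record("Eisenia fetida", "earthworm", c, "LC50", 14, v)
        for c, v in loocv_vals
    ] + [
        _fixture_record("Lumbricus terrestris", "earthworm", c, "LC50", 14, v)
        for c, v in loocv_vals
    ]
    paths["loocv_pair"] = out_dir / "loocv_pair.csv"
    write_records(loocv, paths["loocv_pair"])

    units = [
        _fixture_record("Eisenia fetida", "earthworm", "chem-a", "LC50", 14, 500.0, "mg/kg"),
        _fixture_record("Eisenia fetida", "earthworm", "chem-b", "LC50", 14, 0.5, "g/kg"),
        _fixture_record("Eisenia fetida", "earthworm", "chem-c", "LC50", 14, 500.0, "ug/g"),
        _fixture_record("Eisenia fetida", "earthworm", "chem-d", "LC50", 14, 500.0, "ppm"),
        _fixture_record("Eisenia fetida", "earthworm", "chem-e", "LC50", 14, 500000.0, "ug/kg"),
        _fixture_record("Eisenia fetida", "earthworm", "chem-f", "LC50", 14, 500000.0, "ppb"),
    ]
    paths["unit_variety"] = out_dir / "unit_variety.csv"
    write_records(units, paths["unit_variety"])

    sub = [
        _fixture_record("Eisenia fetida", "earthworm", c, "LC50", 14, v)
        for c, v in [("chem-a", 10.0), ("chem-b", 100.0), ("chem-c", 1000.0)]
    ] + [
        _fixture_record("Eisenia andrei", "earthworm", c, "LC50", 14, v)
        for c, v in [("chem-a", 15.0), ("chem-b", 120.0), ("chem-c", 900.0)]
    ] + [
        # only two chemicals: below the min-chemicals rule, must be dropped
        _fixture_record("Lumbricus rubellus", "earthworm", c, "LC50", 14, v)
        for c, v in [("chem-a", 30.0), ("chem-b", 300.0)]
    ]
    paths["subthreshold"] = out_dir / "subthreshold.csv"
    write_records(sub, paths["subthreshold"])
    return paths
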