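"""End-to-end orchestration: curate -> build -> validate -> summarize.

``run_pipeline`` takes a raw record CSV and a :class:`RunConfig` and writes
the full artifact set: the SMAV table, the directed model table with the
cross-validation column, the hold-out table, the per-group success-rate
means, and a machine-readable counts block on the logging channel.  The
pipeline is fully deterministic: identical inputs and configuration produce
byte-identical output tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import pandas as pd
import yaml

from .curation import CurationConfig, compute_smavs, filter_acute, filter_min_chemicals, smavs_to_frame
from .errors import EligibilityError, ModelLookupError
from .ice import ICEModel, enumerate_pairs, fit_ice, predict_toxicity
from .records import normalize_records, parse_records
from .validation import loocv, summarize_models, taxonomy_classifier

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and options of a full pipeline run."""

    curation: CurationConfig = field(default_factory=CurationConfig)
    alpha: float = 0.05
    min_pair_n: int = 3
    min_loocv_n: int = 4
    fold_k: float = 5.0
    endpoint_types: tuple[str, ...] = ("LC50", "LOEC")
    weighting: str = "model"

    def __post_init__(self) -> None:
        if not (self.min_loocv_n >= self.min_pair_n >= 3):
            raise ValueError("need min_loocv_n >= min_pair_n >= 3")
        if self.fold_k <= 1:
            raise ValueError("fold_k must be > 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        self.endpoint_types = tuple(self.endpoint_types)

    def to_dict(self) -> dict:
        return {
            "curation": self.curation.to_dict(),
            "alpha": self.alpha,
            "min_pair_n": self.min_pair_n,
            "min_loocv_n": self.min_loocv_n,
            "fold_k": self.fold_k,
            "endpoint_types": list(self.endpoint_types),
            "weighting": self.weighting,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        kwargs = {k: data[k] for k in
                  ("alpha", "min_pair_n", "min_loocv_n", "fold_k", "weighting")
                  if k in data}
        if "curation" in data:
            kwargs["curation"] = CurationConfig.from_dict(data["curation"])
        if "endpoint_types" in data:
            kwargs["endpoint_types"] = tuple(data["endpoint_types"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    smav_table: pd.DataFrame
    model_table: pd.DataFrame
    holdout_table: pd.DataFrame
    group_means: pd.DataFrame
    counts: dict[str, int]


def run_pipeline(
    records_path: Union[str, Path],
    config: RunConfig | None = None,
    out_dir: Union[str, Path, None] = None,
) -> PipelineResult:
    """Run the full record-to-report pipeline; optionally write all tables.

    Stage counts (records in/rejected/normalized/post-filter, SMAVs,
    candidate directed datasets, fitted/significant/validated models) are
    logged and returned for consistency checking.
    """
    config = config or RunConfig()
    records, report = parse_records(records_path)
    normalized, dropped_units = normalize_records(records)
    acute = filter_acute(normalized, config.curation)
    retained = filter_min_chemicals(acute, config.curation.min_chemicals_per_species)
    smavs = compute_smavs(retained)

    taxonomy = {
        r.species_latin: (r.phylum, r.class_, r.order) for r in retained
    }
    classify = taxonomy_classifier(taxonomy)

    models: list[ICEModel] = []
    summaries = []
    holdout_rows = []
    n_candidates = 0
    for endpoint in config.endpoint_types:
        datasets = enumerate_pairs(smavs, endpoint, min_n=config.min_pair_n)
        n_candidates += len(datasets)
        for data in datasets:
            model = fit_ice(data, alpha=config.alpha)
            models.append(model)
            try:
                cv = loocv(
                    data, model,
                    k=config.fold_k, min_n=config.min_loocv_n, alpha=config.alpha,
                )
            except EligibilityError:
                continue
            summaries.append(cv)
            for h in cv.holdouts:
                holdout_rows.append(
                    {
                        "surrogate_species": cv.surrogate_species,
                        "predicted_species": cv.predicted_species,
                        "endpoint_type": cv.endpoint_type,
                        "chemical_id": h.chemical_id,
                        "actual_mg_per_kg": h.actual,
                        "predicted_mg_per_kg": h.predicted,
                        "fold_difference": h.fold_difference,
                        "within_k": h.within_k,
                    }
                )

    model_table, group_means = summarize_models(
        models, summaries, classify, weighting=config.weighting  # type: ignore[arg-type]
    )
    holdout_table = pd.DataFrame(
        holdout_rows,
        columns=[
            "surrogate_species", "predicted_species", "endpoint_type", "chemical_id",
            "actual_mg_per_kg", "predicted_mg_per_kg", "fold_difference", "within_k",
        ],
    )
    counts = {
        "records_in": report.n_rows,
        "records_rejected": report.n_rejected,
        "records_parsed": report.n_accepted,
        "records_unit_excluded": len(dropped_units),
        "records_normalized": len(normalized),
        "records_acute": len(acute),
        "records_post_min_chemicals": len(retained),
        "smavs": len(smavs),
        "candidate_datasets": n_candidates,
        "fitted_models": len(models),
        "significant_models": sum(1 for m in models if m.significant),
        "validated_models": len(summaries),
    }
    for key, value in counts.items():
        logger.info("count %s=%d", key, value)

    result = PipelineResult(
        smav_table=smavs_to_frame(smavs),
        model_table=model_table,
        holdout_table=holdout_table,
        group_means=group_means,
        counts=counts,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.smav_table.to_csv(out_dir / "smavs.csv", index=False)
        result.model_table.to_csv(out_dir / "models.csv", index=False)
        result.holdout_table.to_csv(out_dir / "cross_validation.csv", index=False)
        result.group_means.to_csv(out_dir / "group_means.csv", index=False)
    return result


def predict_from_table(
    model_table: pd.DataFrame,
    surrogate_species: str,
    predicted_species: str,
    endpoint_type: str,
    surrogate_value: float,
) -> tuple[float, pd.Series]:
    """Evaluate a fitted model from a model table on a surrogate value
    (mg/kg).  Returns (prediction in mg/kg, the model's table row)."""
    mask = (
        (model_table["surrogate_species"] == surrogate_species)
        & (model_table["predicted_species"] == predicted_species)
        & (model_table["endpoint_type"] == endpoint_type)
    )
    hits = model_table[mask]
    if hits.empty:
        available = sorted(
            model_table[["surrogate_species", "predicted_species", "endpoint_type"]]
            .itertuples(index=False, name=None)
        )
        raise ModelLookupError(
            f"no model {surrogate_species!r} -> {predicted_species!r} [{endpoint_type}]; "
            f"available: {available}"
        )
    row = hits.iloc[0]
    model = ICEModel(
        surrogate_species=surrogate_species,
        predicted_species=predicted_species,
        endpoint_type=endpoint_type,
        slope_a=float(row["slope"]),
        intercept_b=float(row["intercept"]),
        r_squared=float(row["r_squared"]),
        mse=float(row["mse"]),
        p_value=float(row["p_value"]),
        n=int(row["n"]),
        significant=bool(row["significant"]),
    )
    return predict_toxicity(model, surrogate_value), row
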