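"""Leave-one-out cross-validation and fold-difference prediction accuracy.

Model accuracy is assessed by removing one chemical at a time, refitting the
regression on the remaining points, and predicting the removed SMAV.  The
fold difference between the back-transformed (mg/kg scale, never log space)
prediction and the measured value — whichever ratio is >= 1 — summarizes
each hold-out, and the percentage of hold-outs within 5-fold is the model's
prediction success rate.  Values within 5-fold of each other are within the
range of interlaboratory variation for these assays, so the 5-fold bound is
treated as inclusive.

Only significant models (p below the configured alpha) with at least four
data points are eligible; eligibility is decided once on the full-data model
and hold-out refits are not re-tested for significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

import pandas as pd

from .errors import EligibilityError, SoilIceError, UndefinedStatisticError
from .ice import ICEModel, PairedDataset, fit_ice, predict_toxicity


@dataclass(frozen=True)
class HoldOutResult:
    """One LOOCV hold-out: the refit model's prediction vs the measured SMAV."""

    chemical_id: str
    actual: float
    predicted: float
    fold_difference: float
    within_k: bool


@dataclass(frozen=True)
class CrossValidationSummary:
    surrogate_species: str
    predicted_species: str
    endpoint_type: str
    holdouts: tuple[HoldOutResult, ...]
    k: float
    success_rate: float

    @property
    def n(self) -> int:
        return len(self.holdouts)


def fold_difference(predicted: float, actual: float) -> float:
    """Ratio of predicted to actual (or its inverse) so the result is >= 1."""
    if predicted <= 0 or actual <= 0:
        raise ValueError("fold difference requires strictly positive values")
    return max(predicted / actual, actual / predicted)


def success_rate(holdouts: Sequence[HoldOutResult], k: float) -> float:
    """Percentage of hold-outs whose fold difference is within ``k`` (inclusive)."""
    if not holdouts:
        raise UndefinedStatisticError("success rate is undefined for an empty hold-out list")
    n_ok = sum(1 for h in holdouts if h.fold_difference <= k)
    return 100.0 * n_ok / len(holdouts)


def loocv(
    data: PairedDataset,
    model: ICEModel,
    k: float = 5.0,
    min_n: int = 4,
    alpha: float = 0.05,
) -> CrossValidationSummary:
    """Leave-one-out cross-validation of an eligible ICE model.

    Each of the n chemicals is held out once; the model is refit on the
    remaining n - 1 points and the held-out value predicted and compared on
    the mg/kg scale.  Deterministic: no randomness anywhere.
    """
    if not model.significant or model.n < min_n:
        raise EligibilityError(
            f"{model.surrogate_species} -> {model.predicted_species}: model is "
            f"{'not significant' if not model.significant else ''}"
            f"{' and ' if (not model.significant and model.n < min_n) else ''}"
            f"{f'n={model.n} < {min_n}' if model.n < min_n else ''}"
            " — ineligible for cross-validation"
        )
    if model.n != data.n:
        raise SoilIceError("model n does not match the paired dataset size")
    holdouts = []
    for chem, x, y in data.points:
        refit = fit_ice(data.drop(chem), alpha=alpha)
        predicted = predict_toxicity(refit, 10.0 ** x)
        actual = 10.0 ** y
        fold = fold_difference(predicted, actual)
        holdouts.append(HoldOutResult(chem, actual, predicted, fold, fold <= k))
    holdouts = tuple(holdouts)
    return CrossValidationSummary(
        surrogate_species=data.surrogate_species,
        predicted_species=data.predicted_species,
        endpoint_type=data.endpoint_type,
        holdouts=holdouts,
        k=k,
        success_rate=success_rate(holdouts, k),
    )


GroupClassifier = Callable[[ICEModel], str]


def taxonomy_classifier(taxonomy: dict[str, tuple[str, str, str]]) -> GroupClassifier:
    """Build a within-/across-taxa classifier from species -> (phylum, class,
    order).  Same order -> within-taxa; different phylum -> across-taxa;
    anything between -> intermediate."""

    def classify(model: ICEModel) -> str:
        ps = taxonomy.get(model.predicted_species)
        ss = taxonomy.get(model.surrogate_species)
        if ps is None or ss is None:
            return "unclassified"
        if ps[2] == ss[2]:
            return "within-taxa"
        if ps[0] != ss[0]:
            return "across-taxa"
        return "intermediate"

    return classify


def summarize_models(
    models: Iterable[ICEModel],
    summaries: Iterable[CrossValidationSummary],
    grouping: GroupClassifier,
    weighting: Literal["model", "prediction"] = "model",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the published model-table layout plus per-group success means.

    Returns ``(table, group_means)``.  ``table`` has one row per directed
    model in the Tables-style column order with the cross-validation success
    column (NaN for ineligible models); rows sharing an unordered species
    pair share a ``model_pair`` number.  ``group_means`` averages success
    rates per (endpoint type, taxa group) — unweighted across models by
    default, or weighted by hold-out count with ``weighting="prediction"``.
    """
    models = list(models)
    summaries = list(summaries)
    by_direction = {
        (s.surrogate_species, s.predicted_species, s.endpoint_type): s for s in summaries
    }
    model_keys = {(m.surrogate_species, m.predicted_species, m.endpoint_type) for m in models}
    for key in by_direction:
        if key not in model_keys:
            raise SoilIceError(f"cross-validation summary without a matching model: {key}")

    pair_numbers: dict[tuple[str, str, str], int] = {}
    rows = []
    for m in models:
        num = pair_numbers.setdefault(m.pair_key, len(pair_numbers) + 1)
        cv = by_direction.get((m.surrogate_species, m.predicted_species, m.endpoint_type))
        rows.append(
            {
                "model_pair": num,
                "predicted_species": m.predicted_species,
                "surrogate_species": m.surrogate_species,
                "endpoint_type": m.endpoint_type,
                "intercept": m.intercept_b,
                "slope": m.slope_a,
                "r_squared": m.r_squared,
                "p_value": m.p_value,
                "mse": m.mse,
                "n": m.n,
                "significant": m.significant,
                "taxa_group": grouping(m),
                "cross_validation_within_5fold": (
                    round(cv.success_rate, 2) if cv is not None else float("nan")
                ),
                "cv_n": cv.n if cv is not None else 0,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "model_pair", "predicted_species", "surrogate_species", "endpoint_type",
            "intercept", "slope", "r_squared", "p_value", "mse", "n", "significant",
            "taxa_group", "cross_validation_within_5fold", "cv_n",
        ],
    )

    validated = table.dropna(subset=["cross_validation_within_5fold"])
    means_rows = []
    for (endpoint, group), sub in validated.groupby(["endpoint_type", "taxa_group"], sort=True):
        if weighting == "model":
            mean = sub["cross_validation_within_5fold"].mean()
        else:
            mean = (
                sub["cross_validation_within_5fold"] * sub["cv_n"]
            ).sum() / sub["cv_n"].sum()
        means_rows.append(
            {
                "endpoint_type": endpoint,
                "taxa_group": group,
                "n_models": len(sub),
                "mean_success_rate": round(float(mean), 2),
            }
        )
    group_means = pd.DataFrame(
        means_rows, columns=["endpoint_type", "taxa_group", "n_models", "mean_success_rate"]
    )
    return table, group_means
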