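"""Directed species-pair datasets and the ICE log-linear regression.

An interspecies correlation estimation (ICE) model relates the sensitivities
of two soil species through

    log10(predicted toxicity) = a * log10(surrogate toxicity) + b

fitted by ordinary least squares over the chemicals with an SMAV for both
species at the same endpoint type.  Every unordered species pair yields two
directed models (each species takes a turn as the surrogate).  The forward
and reverse fits share R^2 and p-value exactly, and their slopes multiply to
R^2 — an identity of simple least squares that the model tables make visible.

The fit is computed from the normal equations in closed form; the slope
p-value is the two-sided t-test of slope = 0 on n - 2 degrees of freedom
(equivalent to the regression F-test in simple regression), and MSE is the
residual mean square SSE / (n - 2).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .curation import SMAV
from .errors import (
    DegeneratePredictorError,
    InsufficientDataError,
    InvalidPairError,
)

#: Smallest representable positive float, reported as the p-value of an
#: exactly collinear fit (SSE = 0, where the t statistic diverges).
_MIN_P = math.ulp(0.0)


@dataclass(frozen=True)
class PairedDataset:
    """Per-chemical log10-SMAV pairs for one directed species pair.

    ``points`` holds (chemical_id, x, y) with x the log10 surrogate SMAV and
    y the log10 predicted-species SMAV, both in log10 mg/kg; each chemical
    appears at most once.
    """

    surrogate_species: str
    predicted_species: str
    endpoint_type: str
    points: tuple[tuple[str, float, float], ...]

    @property
    def n(self) -> int:
        return len(self.points)

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.points:
            return np.empty(0), np.empty(0)
        arr = np.array([(p[1], p[2]) for p in self.points], dtype=float)
        return arr[:, 0], arr[:, 1]

    def reversed(self) -> "PairedDataset":
        """Swap surrogate and predicted roles (x and y exchange)."""
        return PairedDataset(
            surrogate_species=self.predicted_species,
            predicted_species=self.surrogate_species,
            endpoint_type=self.endpoint_type,
            points=tuple((c, y, x) for c, x, y in self.points),
        )

    def drop(self, chemical_id: str) -> "PairedDataset":
        return PairedDataset(
            self.surrogate_species,
            self.predicted_species,
            self.endpoint_type,
            tuple(p for p in self.points if p[0] != chemical_id),
        )


@dataclass(frozen=True)
class ICEModel:
    """A fitted directed ICE regression and its fit statistics."""

    surrogate_species: str
    predicted_species: str
    endpoint_type: str
    slope_a: float
    intercept_b: float
    r_squared: float
    mse: float
    p_value: float
    n: int
    significant: bool

    @property
    def pair_key(self) -> tuple[str, str, str]:
        """Unordered species pair plus endpoint; shared by both directions."""
        a, b = sorted([self.surrogate_species, self.predicted_species])
        return (a, b, self.endpoint_type)


def pair_species(
    smavs: list[SMAV], surrogate: str, predicted: str, endpoint_type: str
) -> PairedDataset:
    """Pair SMAVs by chemical between a surrogate and a predicted species.

    Only chemicals with an SMAV for *both* species at this endpoint type
    contribute a point; x and y are base-10 logarithms of the SMAVs.
    """
    if surrogate == predicted:
        raise InvalidPairError(f"surrogate and predicted species are identical: {surrogate!r}")
    by_chem_s = {
        s.chemical_id: s.value
        for s in smavs
        if s.species_latin == surrogate and s.endpoint_type == endpoint_type
    }
    by_chem_p = {
        s.chemical_id: s.value
        for s in smavs
        if s.species_latin == predicted and s.endpoint_type == endpoint_type
    }
    shared = sorted(set(by_chem_s) & set(by_chem_p))
    points = tuple(
        (c, math.log10(by_chem_s[c]), math.log10(by_chem_p[c])) for c in shared
    )
    return PairedDataset(surrogate, predicted, endpoint_type, points)


def enumerate_pairs(
    smavs: list[SMAV], endpoint_type: str, min_n: int = 3
) -> list[PairedDataset]:
    """All directed datasets for species pairs sharing >= ``min_n`` chemicals.

    Both directions are emitted for every qualifying unordered pair, ordered
    alphabetically by (surrogate, predicted).
    """
    if min_n < 3:
        raise ValueError("min_n must be >= 3")
    species = sorted(
        {s.species_latin for s in smavs if s.endpoint_type == endpoint_type}
    )
    out: list[PairedDataset] = []
    for a, b in itertools.combinations(species, 2):
        fwd = pair_species(smavs, a, b, endpoint_type)
        if fwd.n >= min_n:
            out.append(fwd)
            out.append(fwd.reversed())
    out.sort(key=lambda d: (d.surrogate_species, d.predicted_species))
    return out


def fit_ice(data: PairedDataset, alpha: float = 0.05) -> ICEModel:
    """Fit the ICE regression by ordinary least squares.

    Raises :class:`InsufficientDataError` for n < 3 and
    :class:`DegeneratePredictorError` when the surrogate values have no
    variance.  An exactly collinear dataset (SSE = 0) is reported with
    r_squared = 1 and the smallest representable positive p-value.
    """
    n = data.n
    if n < 3:
        raise InsufficientDataError(
            f"{data.surrogate_species} -> {data.predicted_species}: "
            f"need at least 3 paired chemicals, have {n}"
        )
    x, y = data.xy()
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0.0:
        raise DegeneratePredictorError(
            "surrogate log-toxicity values are all identical; slope is unidentifiable"
        )
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    sst = float(((y - ybar) ** 2).sum())

    # Relative floor: a fit indistinguishable from exact collinearity.
    if sse <= 1e-14 * max(sst, 1.0):
        r2, mse, p = 1.0, 0.0, _MIN_P
    else:
        r2 = 1.0 - sse / sst
        mse = sse / (n - 2)
        se_slope = math.sqrt(mse / sxx)
        t = slope / se_slope
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
        p = max(p, _MIN_P)
    return ICEModel(
        surrogate_species=data.surrogate_species,
        predicted_species=data.predicted_species,
        endpoint_type=data.endpoint_type,
        slope_a=slope,
        intercept_b=intercept,
        r_squared=r2,
        mse=mse,
        p_value=p,
        n=n,
        significant=p < alpha,
    )


def predict_toxicity(model: ICEModel, surrogate_value: float) -> float:
    """Back-transformed prediction in mg/kg from a surrogate value in mg/kg."""
    if surrogate_value <= 0:
        raise ValueError(f"surrogate_value must be positive, got {surrogate_value}")
    return 10.0 ** (model.slope_a * math.log10(surrogate_value) + model.intercept_b)


def models_to_frame(models: list[ICEModel]) -> pd.DataFrame:
    """Model table with the published column order (cross-validation column
    appended by the validation stage).  Values are unrounded."""
    pair_numbers: dict[tuple[str, str, str], int] = {}
    rows = []
    for m in models:
        num = pair_numbers.setdefault(m.pair_key, len(pair_numbers) + 1)
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
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "model_pair", "predicted_species", "surrogate_species", "endpoint_type",
            "intercept", "slope", "r_squared", "p_value", "mse", "n", "significant",
        ],
    )


def round_sig(value: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if value == 0:
        return 0.0
    return round(value, -int(math.floor(math.log10(abs(value)))) + (sig - 1))


def format_model_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Presentation rounding: coefficients and fit statistics to 2 decimals,
    p-values to 3 significant figures.  Internal values stay unrounded."""
    out = frame.copy()
    for col in ("intercept", "slope", "r_squared", "mse"):
        out[col] = out[col].map(lambda v: round(v, 2))
    out["p_value"] = out["p_value"].map(lambda v: round_sig(v, 3))
    return out
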