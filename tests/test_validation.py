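"""Fold differences, leave-one-out cross-validation, and model summaries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soilice import (
    EligibilityError,
    HoldOutResult,
    PairedDataset,
    UndefinedStatisticError,
    fit_ice,
    fold_difference,
    loocv,
    success_rate,
    summarize_models,
    taxonomy_classifier,
)


def dataset(xs, ys, surrogate="A sp", predicted="B sp", endpoint="LC50"):
    pts = tuple((f"c{i}", float(x), float(y)) for i, (x, y) in enumerate(zip(xs, ys)))
    return PairedDataset(surrogate, predicted, endpoint, pts)


def holdout(fold):
    return HoldOutResult("c", 1.0, fold, fold, fold <= 5)


class TestFoldDifference:
    @pytest.mark.parametrize(
        "pred, actual, expected",
        [(10, 10, 1), (50, 10, 5), (2, 1000, 500)],
    )
    def test_values(self, pred, actual, expected):
        assert fold_difference(pred, actual) == pytest.approx(expected)

    @given(a=st.floats(min_value=1e-6, max_value=1e6),
           b=st.floats(min_value=1e-6, max_value=1e6))
    def test_symmetric_and_at_least_one(self, a, b):
        f = fold_difference(a, b)
        assert f >= 1.0
        assert f == pytest.approx(fold_difference(b, a))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_difference(0, 1)


class TestSuccessRate:
    def test_two_of_three_within(self):
        assert success_rate([holdout(1), holdout(2), holdout(6)], 5) == pytest.approx(
            200 / 3
        )

    def test_all_within(self):
        assert success_rate([holdout(1)] * 4, 5) == 100.0

    def test_boundary_inclusive(self):
        assert success_rate([holdout(5.0)], 5) == 100.0

    def test_empty_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            success_rate([], 5)

    def test_monotone_in_k(self):
        folds = [holdout(f) for f in (1, 2, 4.9, 5.1, 30)]
        rates = [success_rate(folds, k) for k in (1, 2, 5, 10, 50)]
        assert rates == sorted(rates)


class TestLOOCV:
    def test_four_point_model_gets_four_holdouts(self):
        ds = dataset([0, 1, 2, 3], [0.05, 1.1, 1.95, 3.02])
        model = fit_ice(ds)
        cv = loocv(ds, model)
        assert cv.n == model.n == 4
        assert {h.chemical_id for h in cv.holdouts} == {"c0", "c1", "c2", "c3"}

    def test_collinear_data_perfect_success(self):
        ds = dataset([0, 1, 2, 3], [0, 1, 2, 3])
        cv = loocv(ds, fit_ice(ds))
        assert all(h.fold_difference == pytest.approx(1.0) for h in cv.holdouts)
        assert cv.success_rate == 100.0

    def test_matches_exhaustive_refit_oracle(self):
        """Each hold-out prediction equals a manual closed-form OLS refit on
        the remaining points, back-transformed to mg/kg."""
        rng = np.random.default_rng(3)
        for n in (4, 5, 6):
            x = rng.normal(2, 1, n)
            y = 0.9 * x + rng.normal(0, 0.2, n)
            ds = dataset(x, y)
            cv = loocv(ds, fit_ice(ds))
            for i, h in enumerate(cv.holdouts):
                keep = [j for j in range(n) if j != i]
                slope, intercept = np.polyfit(x[keep], y[keep], 1)
                expected = 10 ** (slope * x[i] + intercept)
                assert h.predicted == pytest.approx(expected, rel=1e-9)
                assert h.actual == pytest.approx(10 ** y[i], rel=1e-12)

    def test_deterministic(self):
        ds = dataset([0, 1, 2, 3, 4], [0.2, 0.9, 2.1, 3.2, 3.9])
        model = fit_ice(ds)
        assert loocv(ds, model) == loocv(ds, model)

    def test_nonsignificant_model_ineligible(self):
        ds = dataset([0, 1, 2, 3], [1.0, -0.5, 0.8, 0.1])
        model = fit_ice(ds)
        assert not model.significant
        with pytest.raises(EligibilityError):
            loocv(ds, model)

    def test_three_point_model_ineligible(self):
        ds = dataset([0, 1, 2], [0.1, 1.0, 2.1])
        model = fit_ice(ds)
        with pytest.raises(EligibilityError):
            loocv(ds, model, min_n=4)


class TestSummaries:
    TAXONOMY = {
        "A sp": ("Annelida", "Clitellata", "Opisthopora"),
        "B sp": ("Annelida", "Clitellata", "Opisthopora"),
        "F sp": ("Arthropoda", "Collembola", "Entomobryomorpha"),
    }

    def _model_and_cv(self, surrogate, predicted, seed=0, n=5):
        rng = np.random.default_rng(seed)
        x = rng.normal(2, 1, n)
        y = x + rng.normal(0, 0.05, n)
        ds = dataset(x, y, surrogate=surrogate, predicted=predicted)
        model = fit_ice(ds)
        return ds, model, loocv(ds, model)

    def test_group_means_unweighted(self):
        _, m1, cv1 = self._model_and_cv("A sp", "B sp", seed=1)
        _, m2, cv2 = self._model_and_cv("B sp", "A sp", seed=2)
        table, means = summarize_models(
            [m1, m2], [cv1, cv2], taxonomy_classifier(self.TAXONOMY)
        )
        assert list(table["model_pair"]) == [1, 1]
        expected = (cv1.success_rate + cv2.success_rate) / 2
        row = means[means["taxa_group"] == "within-taxa"].iloc[0]
        assert row["mean_success_rate"] == pytest.approx(round(expected, 2))

    def test_across_taxa_classification(self):
        _, m, cv = self._model_and_cv("A sp", "F sp", seed=3)
        table, means = summarize_models([m], [cv], taxonomy_classifier(self.TAXONOMY))
        assert table["taxa_group"].iloc[0] == "across-taxa"
        assert means["n_models"].iloc[0] == 1
        assert means["mean_success_rate"].iloc[0] == pytest.approx(
            round(cv.success_rate, 2)
        )

    def test_mean_of_two_known_rates(self):
        _, m1, cv1 = self._model_and_cv("A sp", "B sp", seed=1)
        _, m2, cv2 = self._model_and_cv("B sp", "A sp", seed=2)
        object.__setattr__(cv1, "success_rate", 100.0)
        object.__setattr__(cv2, "success_rate", 91.67)
        _, means = summarize_models(
            [m1, m2], [cv1, cv2], taxonomy_classifier(self.TAXONOMY)
        )
        assert means["mean_success_rate"].iloc[0] == pytest.approx(95.84)

    def test_orphan_summary_is_consistency_error(self):
        _, m, cv = self._model_and_cv("A sp", "B sp", seed=1)
        from soilice import SoilIceError

        with pytest.raises(SoilIceError):
            summarize_models([], [cv], taxonomy_classifier(self.TAXONOMY))

    def test_ineligible_model_row_has_nan_success(self):
        ds = dataset([0, 1, 2], [0.1, 1.0, 2.1], surrogate="A sp", predicted="B sp")
        m = fit_ice(ds)
        table, means = summarize_models([m], [], taxonomy_classifier(self.TAXONOMY))
        assert math.isnan(table["cross_validation_within_5fold"].iloc[0])
        assert means.empty
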