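"""Baseline scaling, benchmark prediction, aggregation and adjustment."""

import numpy as np
import pandas as pd
import pytest

from prevadjust import (
    CellTable,
    ModelDesign,
    aggregate,
    estimate_prevalence,
    fit_regions,
    naive_scaled_estimate,
    predict_national,
    relative_adjustment,
)
from prevadjust.datamodel import MEMBER_AUX_PREFIX, NATIONAL_AUX_PREFIX
from prevadjust.estimate import EstimationError
from prevadjust.lmm import build_design

from conftest import build_tiny_frame


class TestNaiveBaseline:
    def test_demographic_scaling_arithmetic(self, tiny_frame):
        tiny_frame.loc[0, ["n_national", "n_member", "y_member"]] = [100, 50, 5]
        est = naive_scaled_estimate(CellTable(tiny_frame))
        assert est.iloc[0] == pytest.approx(10.0)

    def test_full_coverage_returns_member_count(self, tiny_frame):
        tiny_frame["n_national"] = tiny_frame["n_member"]
        tiny_frame["y_national_true"] = np.maximum(
            tiny_frame["y_national_true"], tiny_frame["y_member"]
        )
        est = naive_scaled_estimate(CellTable(tiny_frame))
        np.testing.assert_allclose(est.to_numpy(), tiny_frame["y_member"].to_numpy())

    def test_empty_cells_undefined(self, tiny_frame):
        tiny_frame.loc[0, ["n_member", "y_member"]] = 0
        est = naive_scaled_estimate(CellTable(tiny_frame))
        assert np.isnan(est.iloc[0]) and not np.isnan(est.iloc[1])


class TestBenchmarkIdentity:
    def test_identical_populations_reproduce_member_fit(self, small_pop, design):
        """When the national auxiliary data and sizes coincide with the
        member data, the two-step estimator returns the member fitted
        values exactly (no clamping triggered)."""
        f = small_pop.table.frame.copy()
        f["n_national"] = f["n_member"]
        f["y_national_true"] = f["y_member"]
        for lab in small_pop.table.aux_labels:
            f[NATIONAL_AUX_PREFIX + lab] = f[MEMBER_AUX_PREFIX + lab]
        table = CellTable(f, aux_labels=small_pop.table.aux_labels)
        fits = fit_regions(table, design)
        ptable = estimate_prevalence(table, design, fits=fits)
        fitted = np.concatenate([fits[mr].fitted for mr in sorted(fits)])
        assert not ptable.cells["clamped"].any()
        np.testing.assert_allclose(
            ptable.cells["y_hat_raw"].to_numpy(), fitted, rtol=1e-8
        )

    def test_fixed_effect_only_view(self, small_pop, design):
        fits = fit_regions(small_pop.table, design)
        dm = build_design(small_pop.table, 1, design, "national", check_rank=False)
        pred, _ = predict_national(fits[1], dm)
        zpart = np.array([fits[1].b_hat[d][0] for d in dm.district_ids])
        np.testing.assert_allclose(
            pred - zpart[dm.district_codes], dm.X @ fits[1].beta_hat, rtol=1e-10
        )

    def test_column_mismatch_rejected(self, small_pop, design):
        fits = fit_regions(small_pop.table, design)
        other = ModelDesign(fixed_effects=["intercept", "cell_size"])
        dm = build_design(small_pop.table, 1, other, "national", check_rank=False)
        with pytest.raises(EstimationError, match="mismatch"):
            predict_national(fits[1], dm)


class TestAggregation:
    def _cells(self):
        return pd.DataFrame({
            "region": [1, 1], "district": [1, 1], "cell": [1, 2],
            "age_group": ["I", "I"], "sex": ["female", "male"],
            "n_national": [100.0, 100.0], "n_member": [50, 40],
            "y_member": [4, 2], "y_hat": [8.0, 4.0],
            "naive_estimate": [8.0, 5.0],
        })

    def test_two_cell_arithmetic(self):
        nat = aggregate(self._cells(), "national")
        assert nat["prevalence"].iloc[0] == pytest.approx(0.06)

    def test_single_cell_equals_cell(self):
        one = aggregate(self._cells().iloc[[0]], "district")
        assert one["y_hat"].iloc[0] == 8.0
        assert one["prevalence"].iloc[0] == pytest.approx(0.08)

    def test_unknown_level_rejected(self):
        with pytest.raises(EstimationError, match="unknown aggregation level"):
            aggregate(self._cells(), "continent")

    def test_additivity_across_nested_paths(self, small_pop, design):
        """National prevalence from district aggregates equals the value
        from direct cell-level aggregation to 1e-12."""
        ptable = estimate_prevalence(small_pop.table, design)
        dist = ptable.aggregates["district"]
        via_district = dist["y_hat"].sum() / dist["n_national"].sum()
        assert ptable.national_prevalence == pytest.approx(via_district, abs=1e-12)
        for level in ("region", "age_group", "sex"):
            agg = ptable.aggregates[level]
            assert agg["y_hat"].sum() == pytest.approx(
                ptable.cells["y_hat"].sum(), abs=1e-9
            )


class TestRelativeAdjustment:
    def test_no_change_is_zero(self):
        assert relative_adjustment(0.10, 0.10) == pytest.approx(0.0)

    def test_downward_adjustment(self):
        assert relative_adjustment(0.10, 0.08) == pytest.approx(-20.0)

    def test_zero_member_prevalence_undefined(self):
        assert np.isnan(relative_adjustment(0.0, 0.08))

    def test_adjustment_sign_opposes_planted_gap(self, small_pop, design):
        """Members are sicker by construction, so the adjustment from the
        member prevalence to the national estimate must be negative."""
        ptable = estimate_prevalence(small_pop.table, design)
        assert ptable.national_relative_adjustment < -10.0


class TestDegenerateCells:
    def test_zero_member_district_predicted_and_flagged(self, small_pop, design):
        """Cells with zero members still receive predictions; an entire
        member-free district falls back to fixed effects and is flagged."""
        f = small_pop.table.frame.copy()
        mask = (f["region"] == 2) & (f["district"] == 4)
        f.loc[mask, ["n_member", "y_member"]] = 0
        table = CellTable(f, aux_labels=small_pop.table.aux_labels)
        ptable = estimate_prevalence(table, design)
        sub = ptable.cells[mask.to_numpy()]
        assert sub["y_hat"].notna().all()
        assert sub["fixed_effects_only"].all()
        assert sub["empty_member"].all()
        assert not ptable.cells.loc[~mask.to_numpy(), "fixed_effects_only"].any()

    def test_predictions_clamped_into_range(self, small_pop, design):
        """An extreme national auxiliary value drives the linear prediction
        above N; the reported estimate is clamped and flagged."""
        f = small_pop.table.frame.copy()
        lab = "E11_secondary"
        f.loc[f.index[0], NATIONAL_AUX_PREFIX + lab] = 1e7
        table = CellTable(f, aux_labels=small_pop.table.aux_labels)
        ptable = estimate_prevalence(table, design)
        cells = ptable.cells
        assert cells["clamped"].iloc[0]
        assert (cells["y_hat"] <= cells["n_national"]).all()
        assert (cells["y_hat"] >= 0).all()
        assert cells["y_hat_raw"].iloc[0] > cells["n_national"].iloc[0]
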