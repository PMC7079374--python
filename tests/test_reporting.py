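import numpy as np
import pytest

import cariesflow as cf
from cariesflow.reporting import (MEAN_DMFT_ANCHORS, RepresentativeDmft,
                                  compare_scenarios, mean_dmft, outcome_report,
                                  percent_change, prevalence, round_half_away,
                                  untreated_fraction)
from cariesflow.state import CATEGORIES, REFERENCE_PROJECTIONS_M

BASE = REFERENCE_PROJECTIONS_M["base_case"]
AGG = REFERENCE_PROJECTIONS_M["aggressive"]


class TestPrevalence:
    def test_reference_2010_distribution(self, category_state_builder):
        state = category_state_builder(BASE[2010])
        assert prevalence(state) == pytest.approx(0.6127, abs=5e-4)

    def test_reference_2040_distribution(self, category_state_builder):
        state = category_state_builder(BASE[2040])
        assert prevalence(state) == pytest.approx(0.7491, abs=5e-4)

    def test_all_very_low_is_zero(self):
        counts = np.zeros((4, 2, 2, 2, 2))
        counts[0] = 1.0
        assert prevalence(cf.StockState(2010, counts)) == 0.0

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            prevalence(cf.StockState(2010, np.zeros((4, 2, 2, 2, 2))))


class TestPercentChange:
    def test_high_category_growth(self):
        assert round_half_away(percent_change(19.79, 12.56)) == 58.0

    def test_moderate_category_growth(self):
        assert round_half_away(percent_change(9.87, 8.37)) == 18.0

    def test_no_change_is_zero(self):
        assert percent_change(3.3, 3.3) == 0.0

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)

    def test_round_half_away_convention(self):
        assert round_half_away(0.5) == 1.0
        assert round_half_away(-0.5) == -1.0
        assert round_half_away(2.345, 2) == 2.35


class TestMeanDmft:
    def test_single_category_returns_representative(self):
        counts = np.zeros((4, 2, 2, 2, 2))
        counts[2] = 1.0  # everyone Moderate
        rep = RepresentativeDmft({"15-34": np.array([0.0, 1.0, 2.0, 3.0]),
                                  "35+": np.array([0.0, 1.0, 2.0, 3.0])})
        assert mean_dmft(cf.StockState(2010, counts), rep, "15-34") == 2.0

    def test_equal_quarters(self):
        counts = np.full((4, 2, 2, 2, 2), 1.0)
        rep = RepresentativeDmft({"15-34": np.array([0.0, 1.0, 2.0, 3.0]),
                                  "35+": np.array([0.0, 1.0, 2.0, 3.0])})
        assert mean_dmft(cf.StockState(2010, counts), rep, "35+") == pytest.approx(1.5)

    def test_calibrated_values_hit_base_year_anchors(self, category_state_builder):
        state = category_state_builder(BASE[2010])
        rep = RepresentativeDmft.calibrated(state)
        assert mean_dmft(state, rep, "15-34") == pytest.approx(2.42, rel=1e-9)
        assert mean_dmft(state, rep, "35+") == pytest.approx(2.22, rel=1e-9)

    def test_representative_values_must_be_ordered(self):
        with pytest.raises(ValueError):
            RepresentativeDmft({"15-34": np.array([1.0, 0.5, 2.0, 3.0]),
                                "35+": np.array([0.0, 1.0, 2.0, 3.0])})


class TestUntreatedFraction:
    def test_all_untreated(self, category_state_builder):
        state = category_state_builder(BASE[2010], treated_fraction=0.0)
        assert untreated_fraction(state, "H") == 1.0

    def test_published_level(self, category_state_builder):
        state = category_state_builder(BASE[2010], treated_fraction=0.09)
        assert untreated_fraction(state, "L") == pytest.approx(0.91)

    def test_all_treated(self, category_state_builder):
        state = category_state_builder(BASE[2010], treated_fraction=1.0)
        assert untreated_fraction(state, "M") == 0.0

    def test_empty_category_flags_nan(self):
        counts = np.zeros((4, 2, 2, 2, 2))
        counts[0] = 1.0
        assert np.isnan(untreated_fraction(cf.StockState(2010, counts), "H"))


class TestScenarioComparison:
    def test_identical_reports_give_zero_differences(self, default_model):
        res = default_model.simulate("base_case")
        rep = outcome_report(res)
        other = rep.copy()
        other["scenario"] = "ssb_tax"
        diff = compare_scenarios({"base_case": rep, "ssb_tax": other})
        assert np.allclose(diff["pct_vs_base_case"], 0.0)

    def test_prevalence_difference_from_reference_columns(
            self, category_state_builder):
        base = prevalence(category_state_builder(BASE[2040]))
        agg = prevalence(category_state_builder(AGG[2040]))
        assert 100 * (agg - base) / base == pytest.approx(-21.1, abs=0.1)

    def test_high_dmft_reduction_from_reference_columns(self):
        assert round_half_away(percent_change(AGG[2040]["H"], BASE[2040]["H"])) == -46.0

    def test_mismatched_years_raise(self, default_model):
        rep = outcome_report(default_model.simulate("base_case"))
        clipped = rep.iloc[:-3].copy()
        clipped["scenario"] = "ssb_tax"
        with pytest.raises(ValueError):
            compare_scenarios({"base_case": rep, "ssb_tax": clipped})

    def test_missing_reference_raises(self, default_model):
        rep = outcome_report(default_model.simulate("ssb_tax"))
        with pytest.raises(ValueError):
            compare_scenarios({"ssb_tax": rep}, against="base_case")


def test_outcome_report_columns(default_model):
    rep = outcome_report(default_model.simulate("base_case"))
    assert {"prevalence", "pop_H", "untreated_L", "mean_dmft_15-34",
            "pct_change_prevalence"} <= set(rep.columns)
    assert len(rep) == 31
    assert rep["prevalence"].between(0, 1).all()
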