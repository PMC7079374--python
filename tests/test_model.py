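import numpy as np
import pytest

import cariesflow as cf
from cariesflow.state import CATEGORIES


class TestConservation:
    @pytest.mark.parametrize("scenario", ["base_case", "ssb_tax", "aggressive"])
    def test_population_balance_every_step(self, default_model, scenario):
        res = default_model.simulate(scenario)
        assert res.max_conservation_residual < 1e-9

    def test_totals_track_synthetic_demography(self, default_model):
        res = default_model.simulate("base_case")
        pop = default_model.inputs.population_total
        for year in res.years:
            assert res.state_at(year).total == pytest.approx(
                pop[int(year)], rel=5e-3)


class TestDegenerateDynamics:
    def test_all_flows_off_gives_constant_state(self, quiescent_model):
        res = quiescent_model.simulate("base_case")
        first = res.states[0].counts
        for s in res.states[1:]:
            assert np.array_equal(s.counts, first)

    def test_single_step_identity(self, quiescent_model):
        ctx = quiescent_model.year_context(
            2010, cf.make_scenario("base_case"), 0.5, 0.529,
            np.zeros((4, 2)), {"low": 0.0, "high": 0.0})
        state = quiescent_model.initial_state
        new, ent, dth = quiescent_model.step(state, ctx, 0.25)
        assert ent == 0.0 and dth == 0.0
        assert np.allclose(new.counts, state.counts)
        assert new.year == pytest.approx(2010.25)


class TestStructuralInvariants:
    def test_non_negativity_along_trajectories(self, default_model):
        for scenario in ("base_case", "aggressive"):
            res = default_model.simulate(scenario)
            for s in res.states:
                assert np.all(s.counts >= 0.0)

    def test_severity_unidirectional_without_demography(self):
        # with entrants, aging and deaths off, VL can only drain and H can
        # only fill: any backward severity flow would violate monotonicity
        inputs = cf.build_population_trajectory(
            {2010: 1.0e6, 2040: 1.0e6}, mortality_config={"mortality_35plus": 0.0})
        model = cf.CariesModel(
            inputs=inputs,
            demography=cf.DemographyParams(aging_rate=0.0, mortality_35plus=0.0),
            initial_state=cf.build_initial_state(total=1.0e6, year=2010),
        )
        res = model.simulate("base_case")
        df = res.category_populations()
        assert np.all(np.diff(df["VL"].values) <= 1e-9)
        assert np.all(np.diff(df["H"].values) >= -1e-9)

    def test_scenario_severity_ordering(self, scenario_runs):
        pb = scenario_runs["base_case"].prevalence()
        pt = scenario_runs["ssb_tax"].prevalence()
        pa = scenario_runs["aggressive"].prevalence()
        for year in range(2019, 2041):
            assert pa[year] < pt[year] < pb[year]

    def test_total_sugar_ordering(self, scenario_runs):
        for year in range(2019, 2041):
            sb = scenario_runs["base_case"].total_sugar(year)
            st_ = scenario_runs["ssb_tax"].total_sugar(year)
            sa = scenario_runs["aggressive"].total_sugar(year)
            assert sa <= st_ <= sb

    def test_step_halving_robustness(self, calibrated_model):
        r1 = calibrated_model.simulate("base_case", dt=0.25)
        r2 = calibrated_model.simulate("base_case", dt=0.125)
        c1 = np.array(list(r1.state_at(2040).category_totals().values()))
        c2 = np.array(list(r2.state_at(2040).category_totals().values()))
        assert np.max(np.abs(c1 - c2) / c2) < 5e-3


class TestScenarioMechanics:
    def test_aggressive_uptake_settles_after_boost(self, default_model):
        res = default_model.simulate("aggressive")
        up = res.uptake_frame()
        late = up[(up.year >= 2030)]
        for (cat, grp), g in late.groupby(["category", "income"]):
            assert g["uptake"].std() < 1e-6
        # the boosted level is 1.5x the unboosted indicated level
        base = default_model.simulate("base_case").uptake_frame()
        b40 = base[base.year == 2040].set_index(["category", "income"])["uptake"]
        a40 = up[up.year == 2040].set_index(["category", "income"])["uptake"]
        assert np.allclose(a40 / b40, 1.5, rtol=1e-6)

    def test_aggressive_nonssb_anchors(self, default_model):
        res = default_model.simulate("aggressive")
        b = res.behavior_frame().set_index("year")
        assert b.loc[2018, "nonssb_low"] == pytest.approx(4.47, abs=0.005)
        assert b.loc[2040, "nonssb_high"] == pytest.approx(8.63, abs=0.005)

    def test_base_case_has_no_price_signal(self, default_model):
        b = default_model.simulate("base_case").behavior_frame()
        assert np.allclose(b["price_change"], 0.0)
        assert np.allclose(b["sugar_content"], 0.15)

    def test_tax_reduces_ssb_consumption_more_for_low_income(self, default_model):
        b = default_model.simulate("ssb_tax").behavior_frame().set_index("year")
        base = default_model.simulate("base_case").behavior_frame().set_index("year")
        for year in (2025, 2040):
            red_low = 1.0 - b.loc[year, "ssb_litres_low"] / base.loc[year, "ssb_litres_low"]
            red_high = 1.0 - b.loc[year, "ssb_litres_high"] / base.loc[year, "ssb_litres_high"]
            assert red_low > red_high > 0.0

    def test_horizon_must_cover_policy_start(self, default_model):
        with pytest.raises(ValueError):
            default_model.simulate("ssb_tax", start=2010, end=2015)

    def test_invalid_dt_rejected(self, default_model):
        with pytest.raises(ValueError):
            default_model.simulate("base_case", dt=0.3)


class TestResultsApi:
    def test_summary_mentions_scenario_and_prevalence(self, default_model):
        res = default_model.simulate("base_case")
        text = res.summary()
        assert "base_case" in text and "prevalence" in text

    def test_tidy_frame_shape(self, default_model):
        res = default_model.simulate("base_case")
        df = res.to_frame()
        assert set(df.columns) >= {"scenario", "year", "category", "persons"}
        assert len(df) == 31 * 64

    def test_with_params_roundtrip(self, default_model):
        m = default_model.with_params(vl_to_l=0.05, sugar_content=0.12,
                                      demand_elasticity_low=-1.0)
        assert m.rates.vl_to_l == 0.05
        assert m.base_sugar_content == 0.12
        assert m.behavior.demand_elasticity["low"] == -1.0
        # original untouched
        assert default_model.rates.vl_to_l == 0.063
        with pytest.raises(KeyError):
            default_model.with_params(not_a_parameter=1.0)
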