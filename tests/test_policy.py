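import numpy as np
import pytest

from cariesflow.policy import (DEFAULT_TAX_SCHEDULE, PriceResponse,
                               make_scenario, reformulated_content,
                               relative_price_change)

SCHED = DEFAULT_TAX_SCHEDULE

# every published cell of the tiered schedule: (content g/100ml, year, Baht)
PRINTED_CELLS = [
    (3.0, 2018, 0.0), (3.0, 2021, 0.0), (3.0, 2023, 0.0), (3.0, 2030, 0.0),
    (7.0, 2018, 0.1), (7.0, 2021, 0.1), (7.0, 2023, 0.3), (7.0, 2030, 1.0),
    (9.0, 2018, 0.3), (9.0, 2021, 0.3), (9.0, 2023, 1.0), (9.0, 2030, 3.0),
    (12.0, 2018, 0.5), (12.0, 2021, 1.0), (12.0, 2023, 3.0), (12.0, 2026, 5.0),
    (16.0, 2018, 1.0), (16.0, 2021, 3.0), (16.0, 2023, 5.0), (16.0, 2030, 5.0),
    (20.0, 2018, 1.0), (20.0, 2021, 5.0), (20.0, 2023, 5.0), (20.0, 2030, 5.0),
]

# tier boundaries resolve per the closed-on-top interval labels
BOUNDARY_CELLS = [
    (5.99, 2030, 0.0), (6.0, 2030, 1.0),
    (8.0, 2030, 1.0), (8.01, 2030, 3.0),
    (10.0, 2030, 3.0), (10.01, 2030, 5.0),
    (14.0, 2030, 5.0), (14.01, 2030, 5.0),
    (18.0, 2030, 5.0), (18.01, 2030, 5.0),
    (14.0, 2018, 0.5), (14.01, 2018, 1.0),
    (18.0, 2021, 3.0), (18.01, 2021, 5.0),
]


class TestTaxSchedule:
    @pytest.mark.parametrize("content,year,expected", PRINTED_CELLS + BOUNDARY_CELLS)
    def test_rate_lookup(self, content, year, expected):
        assert SCHED.tax_rate(content, year) == expected

    @pytest.mark.parametrize("content", [0.0, 5.0, 9.0, 20.0])
    def test_pre_policy_years_are_untaxed(self, content):
        assert SCHED.tax_rate(content, 2017) == 0.0
        assert SCHED.tax_rate(content, 2010) == 0.0

    def test_negative_content_raises(self):
        with pytest.raises(ValueError):
            SCHED.tax_rate(-1.0, 2020)

    def test_lookup_total_over_content_grid(self):
        # every non-negative content maps to exactly one tier
        for c in np.arange(0.0, 30.0, 0.07):
            assert 0 <= SCHED.tier_index(c) <= 5

    def test_monotone_in_year_and_content(self):
        years = [2016, 2018, 2020, 2021, 2022, 2023, 2024, 2025, 2030, 2040]
        contents = np.arange(0.0, 25.0, 0.25)
        for c in contents:
            rates = [SCHED.tax_rate(c, y) for y in years]
            assert np.all(np.diff(rates) >= 0)
        for y in years:
            rates = [SCHED.tax_rate(c, y) for c in contents]
            assert np.all(np.diff(rates) >= 0)

    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd

        rows = []
        lows = [0.0] + [u for u in SCHED.tier_upper[:-1]]
        period_ends = list(SCHED.period_starts[1:]) + [2040]
        for i, hi in enumerate(SCHED.tier_upper):
            for j, y0 in enumerate(SCHED.period_starts):
                rows.append({
                    "tier_low_g_per_100ml": lows[i],
                    "tier_high_g_per_100ml": 1e12 if np.isinf(hi) else hi,
                    "year_start": y0, "year_end": period_ends[j],
                    "baht": SCHED.rates[i, j],
                })
        path = tmp_path / "sched.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        loaded = type(SCHED).from_csv(path)
        for content, year, expected in PRINTED_CELLS:
            assert loaded.tax_rate(content, year) == expected


class TestPriceResponse:
    def test_zero_tax_means_zero_change(self):
        assert relative_price_change(0.0, PriceResponse()) == 0.0

    def test_full_passthrough(self):
        r = PriceResponse(passthrough=1.0, reference_price=20.0)
        assert relative_price_change(2.0, r) == pytest.approx(0.10)

    def test_partial_passthrough(self):
        r = PriceResponse(passthrough=0.5, reference_price=25.0)
        assert relative_price_change(5.0, r) == pytest.approx(0.10)

    def test_zero_reference_price_rejected(self):
        with pytest.raises(ValueError):
            PriceResponse(reference_price=0.0)


class TestReformulation:
    def test_unchanged_before_policy_start(self):
        assert reformulated_content(0.15, PriceResponse(), 2015) == 0.15

    def test_full_phase_in_value(self):
        # 80% cut on the reformulating half of the market: 0.15*(1-0.4)=0.09
        r = PriceResponse(percent_reduce_ssb_sugar=0.8, reformulating_fraction=0.5)
        assert reformulated_content(0.15, r, 2030) == pytest.approx(0.09)

    def test_no_reduction_parameter_means_no_change(self):
        r = PriceResponse(percent_reduce_ssb_sugar=0.0)
        for year in (2018, 2025, 2040):
            assert reformulated_content(0.15, r, year) == 0.15

    def test_untaxed_tier_never_reformulates(self):
        assert reformulated_content(0.05, PriceResponse(), 2030) == 0.05

    def test_content_non_increasing_while_tax_escalates(self):
        r = PriceResponse()
        series = [reformulated_content(0.15, r, y) for y in range(2016, 2041)]
        assert np.all(np.diff(series) <= 1e-15)

    def test_non_positive_content_raises(self):
        with pytest.raises(ValueError):
            reformulated_content(0.0, PriceResponse(), 2030)


class TestScenarios:
    def test_aggressive_settings(self):
        s = make_scenario("aggressive")
        assert s.nonssb_reduction == pytest.approx(0.80)
        assert s.uptake_boost == pytest.approx(1.5)
        assert s.tax_on and s.start_year == 2018

    def test_ssb_tax_settings(self):
        s = make_scenario("ssb_tax")
        assert s.tax_on
        assert s.nonssb_reduction == 0.0
        assert s.uptake_boost == 1.0

    def test_base_case_is_fully_off(self):
        s = make_scenario("base_case")
        assert not s.tax_on
        assert s.nonssb_reduction == 0.0
        assert s.uptake_boost == 1.0

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            make_scenario("laissez_faire")
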