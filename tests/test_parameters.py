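"""Parameter loading, validation, rate conversion and mortality calibration."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wcdcma import (
    LifeTable,
    annual_to_cycle_prob,
    background_monthly_mortality,
    calibrate_excess_cardiac_mortality,
    load_parameters,
    synthetic_life_table,
)
from conftest import flat_life_table, immortal_life_table


class TestLoadParameters:
    def test_printed_cost_inputs_echoed(self, life_table):
        config = {"costs": {"wcd_episode_cost": 3600, "hosp_daily_cost": 250, "hosp_los_days": 21}}
        params = load_parameters(config, life_table)
        assert params.costs.wcd_episode_cost == 3600
        assert params.costs.standard_care_episode_cost == 250 * 21

    def test_empty_config_gives_defaults(self, life_table):
        params = load_parameters(None, life_table)
        assert params.clinical.start_age == 61
        assert params.clinical.event_survival == 0.855
        assert params.clinical.battery_life_months == 60
        assert params.settings.annual_discount_rate == 0.03
        assert params.costs.wcd_episode_cost == 3600.0

    def test_yaml_text_source(self, life_table):
        params = load_parameters("clinical:\n  p_sca_bridge_month: 0.045\n", life_table)
        assert params.clinical.p_sca_bridge_month == 0.045

    def test_probability_out_of_bounds_names_field(self, life_table):
        with pytest.raises(Exception, match="p_procedural_death"):
            load_parameters({"clinical": {"p_procedural_death": 1.2}}, life_table)

    def test_unknown_keys_rejected(self, life_table):
        with pytest.raises(Exception):
            load_parameters({"clinical": {"not_a_parameter": 1}}, life_table)
        with pytest.raises(ValueError, match="unknown config sections"):
            load_parameters({"typo_section": {}}, life_table)

    def test_missing_life_table_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_parameters(None, tmp_path / "nope.csv")

    def test_start_age_must_be_covered(self):
        table = flat_life_table(min_age=60, max_age=110)
        with pytest.raises(Exception, match="start_age"):
            load_parameters({"clinical": {"start_age": 40}}, table)

    def test_life_table_csv_round_trip(self, tmp_path, life_table):
        path = tmp_path / "lt.csv"
        life_table.to_csv(path)
        again = LifeTable.from_csv(path)
        assert again == life_table


class TestLifeTableInvariants:
    def test_non_contiguous_ages_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            LifeTable(ages=(60, 62, 63), q_annual=(0.01, 0.01, 1.0))

    def test_terminal_age_must_be_absorbing(self):
        with pytest.raises(ValueError, match="terminal"):
            LifeTable(ages=(60, 61), q_annual=(0.01, 0.5))


class TestRateConversion:
    @pytest.mark.parametrize(
        "p_annual, cycles, expected",
        [
            (0.0, 12, 0.0),
            (1.0, 12, 1.0),
            (0.03, 12, 1.0 - 0.97 ** (1.0 / 12.0)),  # = 0.002534...
        ],
    )
    def test_closed_form(self, p_annual, cycles, expected):
        assert annual_to_cycle_prob(p_annual, cycles) == pytest.approx(expected, abs=1e-15)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            annual_to_cycle_prob(1.5, 12)
        with pytest.raises(ValueError):
            annual_to_cycle_prob(0.5, 0)

    @settings(max_examples=200, deadline=None)
    @given(p=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_round_trip_over_a_year(self, p):
        """Composing the monthly probability over 12 cycles recovers the annual one."""
        monthly = annual_to_cycle_prob(p, 12)
        assert 1.0 - (1.0 - monthly) ** 12 == pytest.approx(p, abs=1e-12)


class TestBackgroundMortality:
    def test_terminal_age_is_certain_death(self, life_table):
        assert background_monthly_mortality(life_table, life_table.max_age) == 1.0
        assert background_monthly_mortality(life_table, life_table.max_age + 3.5) == 1.0

    def test_immortal_table_gives_zero(self):
        table = immortal_life_table()
        assert background_monthly_mortality(table, 61.0) == 0.0
        assert background_monthly_mortality(table, 80.25) == 0.0

    def test_gompertz_monotone_in_age(self):
        table = synthetic_life_table()
        q61 = background_monthly_mortality(table, 61)
        q80 = background_monthly_mortality(table, 80)
        assert q80 > q61
        ages = [table.min_age + k / 2 for k in range(2 * (table.max_age - table.min_age))]
        values = [background_monthly_mortality(table, a) for a in ages]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_age_floored_to_whole_years(self, life_table):
        assert background_monthly_mortality(life_table, 61.9) == background_monthly_mortality(life_table, 61.0)


class TestExcessMortalityCalibration:
    def test_zero_scd_fraction(self):
        table = flat_life_table(0.01)
        assert calibrate_excess_cardiac_mortality(0.22, 5.0, 0.0, table, 61) == 0.0

    def test_no_excess_when_trial_equals_background(self):
        table = flat_life_table(0.02)
        cum = 1.0 - (1.0 - 0.02) ** 5  # background cumulative mortality over 5 years
        assert calibrate_excess_cardiac_mortality(cum, 5.0, 0.5, table, 61) == 0.0

    def test_hand_computed_hazard_arithmetic(self):
        """Independent step-by-step hazard computation for a trial summary.

        22% cumulative mortality over 5 years against a flat 1%/year
        background, half attributed to sudden cardiac death.
        """
        table = flat_life_table(0.01)
        h_total = -math.log(1.0 - 0.22) / 60.0
        h_bg = -math.log(1.0 - 0.01) / 12.0
        expected = 1.0 - math.exp(-0.5 * (h_total - h_bg))
        got = calibrate_excess_cardiac_mortality(0.22, 5.0, 0.5, table, 61)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.0016503, abs=1e-7)

    @settings(max_examples=60, deadline=None)
    @given(
        cum=st.floats(min_value=0.0, max_value=0.9),
        frac=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone_in_trial_mortality_and_scd_fraction(self, cum, frac):
        table = flat_life_table(0.01)
        base = calibrate_excess_cardiac_mortality(cum, 5.0, frac, table, 61)
        more_mortality = calibrate_excess_cardiac_mortality(min(cum + 0.05, 0.95), 5.0, frac, table, 61)
        more_scd = calibrate_excess_cardiac_mortality(cum, 5.0, min(frac + 0.1, 1.0), table, 61)
        assert more_mortality >= base
        assert more_scd >= base
        assert base >= 0.0
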