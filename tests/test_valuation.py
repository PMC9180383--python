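"""VSL transfer, deflation, discounted schedules, and monetization."""

import numpy as np
import pandas as pd
import pytest

from dioxin_bpt import (
    DiscountConvention,
    DiscountSpec,
    Period,
    ValidationError,
    ValueTransferParams,
    build_vsl_schedule,
    deflate_vsl_real,
    monetize_deaths,
    transfer_vsl_nominal,
)
from dioxin_bpt.fixtures import taiwan


def _params(**overrides) -> ValueTransferParams:
    base = dict(
        vsl_base=11.79,
        earnings_elasticity=0.2476,
        wage_base=1317.18,
        wage_target=1385.64,
        cpi_base=98.93,
        cpi_target=102.55,
        exchange_rate=31.807,
    )
    base.update(overrides)
    return ValueTransferParams(**base)


class TestWageTransfer:
    def test_elasticity_applied_to_percent_wage_change(self):
        # +5.1974% wages x elasticity 0.2476 on 11.79M
        assert transfer_vsl_nominal(_params()) == pytest.approx(11.9417e6, rel=1e-4)

    def test_flat_wages_leave_vsl_unchanged(self):
        params = _params(wage_target=1317.18)
        assert transfer_vsl_nominal(params) == pytest.approx(11.79e6, rel=1e-12)

    def test_zero_elasticity_leaves_vsl_unchanged(self):
        params = _params(earnings_elasticity=0.0)
        assert transfer_vsl_nominal(params) == pytest.approx(11.79e6, rel=1e-12)

    def test_nonpositive_wage_rejected(self):
        with pytest.raises(ValueError):
            _params(wage_base=0.0)


class TestCPIDeflation:
    def test_deflation_factor(self):
        assert deflate_vsl_real(_params(), 11.79e6) == pytest.approx(11.3738e6, rel=1e-4)

    def test_equal_cpis_leave_value_unchanged(self):
        params = _params(cpi_target=98.93)
        assert deflate_vsl_real(params, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_halving(self):
        params = _params(cpi_base=50.0, cpi_target=100.0)
        assert deflate_vsl_real(params, 1.0) == pytest.approx(0.5, rel=1e-12)

    def test_nonpositive_cpi_rejected(self):
        with pytest.raises(ValueError):
            _params(cpi_target=0.0)

    def test_transfer_then_deflate_is_the_composed_factor(self):
        """Both adjustments are multiplicative, so order cannot matter."""
        params = _params()
        nominal = transfer_vsl_nominal(params)
        real = deflate_vsl_real(params, nominal)
        f_wage = 1.0 + params.earnings_elasticity * (
            (params.wage_target - params.wage_base) / params.wage_base
        )
        f_cpi = params.cpi_base / params.cpi_target
        assert real == params.vsl_base * 1e6 * f_wage * f_cpi


class TestVSLSchedule:
    def test_geometric_annual_period_average(self):
        periods = [Period("2021-2025", 2021, 2025)]
        spec = DiscountSpec(annual_rate=0.02, base_year=2020,
                            convention=DiscountConvention.GEOMETRIC_ANNUAL)
        schedule = build_vsl_schedule({"children": 100.0}, periods, spec)
        # (1/5) * sum_{k=1..5} 1.02^-k = 0.942692
        assert schedule.vsl.loc[("children", "2021-2025")] == pytest.approx(
            94.2692, abs=1e-4
        )

    def test_zero_rate_gives_constant_schedule(self):
        periods = [Period("2020", 2020, 2020), Period("2021-2025", 2021, 2025)]
        spec = DiscountSpec(annual_rate=0.0, base_year=2020,
                            convention=DiscountConvention.GEOMETRIC_ANNUAL)
        schedule = build_vsl_schedule({"older": 5.0}, periods, spec)
        assert set(schedule.vsl) == {5.0}

    def test_fixture_convention_returns_published_schedule(self):
        published = taiwan.vsl_schedule().vsl
        spec = DiscountSpec(convention=DiscountConvention.FIXTURE)
        schedule = build_vsl_schedule({}, [], spec, fixture=published)
        assert schedule.vsl.loc[("children", "2021-2025")] == 2_167_689.0

    def test_fixture_convention_requires_a_schedule(self):
        spec = DiscountSpec(convention=DiscountConvention.FIXTURE)
        with pytest.raises(ValidationError, match="fixture"):
            build_vsl_schedule({"children": 1.0}, [], spec)

    def test_nonpositive_base_rejected(self):
        spec = DiscountSpec(convention=DiscountConvention.GEOMETRIC_ANNUAL)
        with pytest.raises(ValidationError):
            build_vsl_schedule({"children": 0.0}, [Period("2020", 2020, 2020)], spec)


def _deaths(values: dict) -> pd.Series:
    s = pd.Series(values)
    s.index = s.index.set_names(["age_group", "region"])
    return s


class TestMonetization:
    def test_national_working_age_base_year(self, taiwan_scenario):
        deaths = _deaths({("working_age", "taiwan"): 2.2977})
        mdc = monetize_deaths(deaths, taiwan_scenario.vsl, "2020")
        assert mdc.iloc[0] == pytest.approx(28_322_862, rel=1e-4)

    def test_southern_children_base_year(self, taiwan_scenario):
        deaths = _deaths({("children", "southern"): 0.172220})
        mdc = monetize_deaths(deaths, taiwan_scenario.vsl, "2020")
        assert mdc.iloc[0] == pytest.approx(377_956, rel=2e-4)

    def test_zero_deaths_zero_value(self, taiwan_scenario):
        deaths = _deaths({("children", "taiwan"): 0.0})
        mdc = monetize_deaths(deaths, taiwan_scenario.vsl, "2020")
        assert mdc.iloc[0] == 0.0

    def test_missing_schedule_cell_named(self, taiwan_scenario):
        deaths = _deaths({("children", "taiwan"): 1.0})
        with pytest.raises(ValidationError) as excinfo:
            monetize_deaths(deaths, taiwan_scenario.vsl, "2999")
        assert "2999" in str(excinfo.value)

    def test_bilinearity(self, small_scenario):
        """Scaling deaths scales every value; scaling one group's VSL scales
        only that group's values."""
        sc = small_scenario
        deaths = _deaths(
            {
                ("children", "region_1"): 1.5,
                ("working_age", "region_1"): 2.5,
                ("older", "region_1"): 0.5,
            }
        )
        period = sc.periods[1]
        base = monetize_deaths(deaths, sc.vsl, period)
        scaled = monetize_deaths(deaths * 3.0, sc.vsl, period)
        np.testing.assert_allclose(scaled.to_numpy(), base.to_numpy() * 3.0, rtol=1e-12)

        vsl2 = sc.vsl.vsl.copy()
        mask = vsl2.index.get_level_values("age_group") == "children"
        vsl2 = vsl2.where(~mask, vsl2 * 7.0)
        from dioxin_bpt import VSLSchedule

        bumped = monetize_deaths(deaths, VSLSchedule(vsl=vsl2), period)
        assert bumped.loc[("children", "region_1")] == pytest.approx(
            base.loc[("children", "region_1")] * 7.0, rel=1e-12
        )
        assert bumped.loc[("older", "region_1")] == base.loc[("older", "region_1")]
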