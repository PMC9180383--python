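import numpy as np
import pandas as pd
import pytest

from dioxin_bpt.fixtures import taiwan
from dioxin_bpt.synthetic import SynthConfig, generate_scenario


@pytest.fixture(scope="session")
def taiwan_scenario():
    return taiwan.scenario()


@pytest.fixture(scope="session")
def taiwan_mdc():
    """The published monetized-mortality table."""
    return taiwan.monetized_mortality()


@pytest.fixture(scope="session")
def taiwan_trajectory():
    return taiwan.emission_trajectory()


@pytest.fixture
def small_scenario():
    """A compact random scenario for oracle and property tests."""
    return generate_scenario(SynthConfig(seed=1234, n_regions=3, n_periods=4))


def brute_force_mdc(scenario):
    """Independent re-computation of the monetized burden by plain loops.

    Multiplies dose x slope factor x population x mortality risk x VSL one
    scalar at a time, without any table machinery.
    """
    out = {}
    for period in scenario.periods:
        for region in scenario.regions:
            for group in scenario.age_groups:
                ladd = float(scenario.exposure.ladd.loc[(group.value, region.id)])
                pop = float(
                    scenario.populations.count.loc[(group.value, region.id, period.id)]
                )
                vsl = float(scenario.vsl.vsl.loc[(group.value, period.id)])
                out[(group.value, region.id, period.id)] = (
                    ladd
                    * scenario.coeffs.csf
                    * pop
                    * scenario.coeffs.mortality_risk
                    * vsl
                )
    series = pd.Series(out)
    series.index = series.index.set_names(["age_group", "region", "period"])
    return series


def assert_rel_close(actual, expected, rtol, atol=0.0, msg=""):
    actual = np.asarray(actual, dtype=float)
    expected = np.asarray(expected, dtype=float)
    np.testing.assert_allclose(actual, expected, rtol=rtol, atol=atol, err_msg=msg)
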