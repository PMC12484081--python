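import pytest

from leadiq import CountryRecord, DoseResponseSpec, EconomicParams, QuadratureSettings


@pytest.fixture
def toy_econ():
    """Hand-computable monetization: 2 IQ pts * 0.02 * (0.09/0.06) * 100 = 6%."""
    return EconomicParams(e_us=0.02, r_us=0.06, cap_pct=100.0)


@pytest.fixture
def linear_dr():
    return DoseResponseSpec(form="linear", coefficients=(0.5,))


@pytest.fixture
def quad():
    return QuadratureSettings()


@pytest.fixture
def toy_records():
    """Two-country world: one exposed at 4 µg/dL, one unexposed."""
    return [
        CountryRecord(
            iso3="AAA", name="Alpha", continent="Africa",
            bll_mean=4.0, bll_lo=3.0, bll_hi=5.0,
            p_gt5=None, p_gt10=None,
            gdp_pc=10_000.0, pop_0_19=1_000_000, ret_edu=0.09,
        ),
        CountryRecord(
            iso3="BBB", name="Beta", continent="Africa",
            bll_mean=0.0, bll_lo=0.0, bll_hi=0.0,
            p_gt5=0.0, p_gt10=0.0,
            gdp_pc=20_000.0, pop_0_19=500_000, ret_edu=0.09,
        ),
    ]
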