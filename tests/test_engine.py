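import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from pharmforecast import (
    DEFAULT_HORIZON,
    ForecastHorizon,
    Product,
    aggregate,
    base_case_parameters,
    innovation_cost_series,
    offpatent_monthly_saving,
    penetration,
    product_saving_series,
    read_portfolio_csv,
    run_forecast,
    to_perspective,
    write_portfolio_csv,
)
from pharmforecast.engine import days_to_months
from pharmforecast.sensitivity import set_parameter


def offpatent(country, sales, share, loe, biologic=False, pid="p"):
    return Product(
        product_id=pid,
        country=country,
        molecule_class="biologic" if biologic else "small_molecule",
        lifecycle="off_patent_candidate",
        annual_sales_2011=sales,
        retail_share=share,
        loe_month=loe,
    )


def pipeline(country, approval, peak, uptake=12, pid="q"):
    return Product(
        product_id=pid,
        country=country,
        molecule_class="small_molecule",
        lifecycle="pipeline",
        approval_month=approval,
        peak_annual_sales=peak,
        uptake_months=uptake,
    )


# --------------------------------------------------------------------------
# elementary operations


@pytest.mark.parametrize(
    "month,entry,max_pen,ramp,expected",
    [
        (5, 10, 0.8, 36, 0.0),  # pre-entry
        (10, 10, 0.8, 0, 0.8),  # zero ramp jumps to the ceiling at entry
        (18, 0, 0.8, 36, 0.4),  # halfway up a 36-month ramp
        (36, 0, 0.8, 36, 0.8),  # ramp completed
        (100, 0, 0.8, 36, 0.8),  # ceiling holds after the ramp
        (30, -30, 1.0, 60, 1.0),  # pre-horizon entry, ramp in progress
    ],
)
def test_penetration(month, entry, max_pen, ramp, expected):
    assert penetration(month, entry, max_pen, ramp) == pytest.approx(expected)


@settings(max_examples=50, derandomize=True)
@given(
    month=st.integers(-24, 120),
    entry=st.integers(-24, 60),
    max_pen=st.floats(0, 1),
    ramp=st.integers(0, 48),
)
def test_penetration_bounded_and_monotone(month, entry, max_pen, ramp):
    p = penetration(month, entry, max_pen, ramp)
    assert 0.0 <= p <= max_pen
    assert penetration(month + 1, entry, max_pen, ramp) >= p


def test_offpatent_monthly_saving_arithmetic():
    assert offpatent_monthly_saving(100, 0.0, 0.6, 0.2, entered=False) == 0.0
    assert offpatent_monthly_saving(100, 0.5, 0.6, 0.2, entered=True) == pytest.approx(40.0)
    # with no originator response the saving is proportional to the discount
    s1 = offpatent_monthly_saving(100, 0.5, 0.3, 0.0, entered=True)
    s2 = offpatent_monthly_saving(100, 0.5, 0.6, 0.0, entered=True)
    assert s2 == pytest.approx(2 * s1)


def test_days_to_months_nearest():
    assert [days_to_months(d) for d in (0, 45, 60, 180, 470, 580)] == [0, 1, 2, 6, 15, 19]


# --------------------------------------------------------------------------
# product series


def test_hospital_only_biologic_constant_saving(base_params):
    product = offpatent("France", 1200.0, 0.0, "2012-01", biologic=True)
    component, series = product_saving_series(product, base_params["France"])
    assert component == "biosimilar_savings"
    assert np.allclose(series, 80.0)  # 100 €/mo base × 100% uptake × 80% discount


def test_uk_retail_generic_reaches_steady_state(base_params):
    product = offpatent("United Kingdom", 1200.0, 1.0, "2012-01")
    component, series = product_saving_series(product, base_params["United Kingdom"])
    assert component == "generic_savings"
    assert series[0] == pytest.approx(0.0)  # ramp starts at zero share
    assert series[12] == pytest.approx(100.0 * 0.8 * 0.75)
    assert np.allclose(series[12:], 60.0)


def test_loe_after_horizon_is_all_zero(base_params):
    product = offpatent("France", 1e9, 0.5, "2017-01")
    _, series = product_saving_series(product, base_params["France"])
    assert not series.any()


def test_series_reject_wrong_lifecycle(base_params):
    with pytest.raises(ValueError):
        product_saving_series(pipeline("France", "2013-01", 1.0), base_params["France"])
    with pytest.raises(ValueError):
        innovation_cost_series(
            offpatent("France", 1.0, 0.5, "2013-01"), base_params["France"]
        )


def test_innovation_first_year_ramp(base_params):
    product = pipeline("Germany", "2012-01", 1200.0, uptake=12)
    _, series = innovation_cost_series(product, base_params["Germany"])
    # k-th month on the market books k/12 of the €100 peak monthly value
    assert series[:12].sum() == pytest.approx(650.0)
    assert np.allclose(series[12:], 100.0)


def test_innovation_delayed_by_brand_ttm(base_params):
    delayed = pipeline("France", "2012-01", 1200.0)  # 12-month brand ttm
    _, series = innovation_cost_series(delayed, base_params["France"])
    assert not series[:12].any() and series[12:].any()
    late = pipeline("France", "2016-06", 1200.0)
    _, late_series = innovation_cost_series(late, base_params["France"])
    assert not late_series.any()  # launch falls beyond the horizon


# --------------------------------------------------------------------------
# aggregation, perspectives, composition


def test_aggregate_yearly_matches_direct_summation():
    rng = np.random.default_rng(3)
    series = rng.normal(size=60)
    result = aggregate([("France", "generic_savings", series)])
    yearly = result.yearly().loc["France", "generic_savings"]
    for i, year in enumerate(range(2012, 2017)):
        assert yearly[year] == pytest.approx(series[12 * i : 12 * (i + 1)].sum())
    assert result.cumulative().loc["France", "generic_savings"] == pytest.approx(
        series.sum()
    )


def test_aggregate_all_zero():
    result = aggregate([("France", "innovation_cost", np.zeros(60))])
    assert (result.yearly() == 0).all().all()


def test_conservation_identity(base_params, small_portfolio):
    result = run_forecast(small_portfolio, base_params)
    yearly = result.yearly()
    np.testing.assert_allclose(
        yearly["net"],
        yearly["innovation_cost"] - yearly["generic_savings"] - yearly["biosimilar_savings"],
    )
    cumulative = result.cumulative()
    np.testing.assert_allclose(
        cumulative["net"], yearly["net"].groupby(level="country").sum()
    )


def test_perspective_scaling(base_params, small_portfolio):
    society = run_forecast(small_portfolio, base_params, perspective="society")
    rates = {c: base_params[c].reimbursement_rate for c in society.countries}
    payer = to_perspective(society, rates, "payer")
    components = ["generic_savings", "biosimilar_savings", "innovation_cost"]
    for country in society.countries:
        # payer = rate × society, exactly, component by component
        np.testing.assert_array_equal(
            payer.yearly().loc[country, components].to_numpy(),
            society.yearly().loc[country, components].to_numpy() * rates[country],
        )
        np.testing.assert_allclose(
            payer.yearly().loc[country, "net"],
            society.yearly().loc[country, "net"] * rates[country],
            rtol=1e-12,
        )
    assert to_perspective(society, 1.0, "payer").yearly().equals(society.yearly())

    manufacturer = to_perspective(society, rates, "manufacturer")
    np.testing.assert_allclose(
        manufacturer.yearly()["generic_savings"],
        -society.yearly()["generic_savings"],
    )
    np.testing.assert_allclose(
        manufacturer.yearly()["innovation_cost"],
        society.yearly()["innovation_cost"],
    )


def test_society_net_scaled_example():
    result = aggregate([("France", "innovation_cost", np.full(60, -100 / 60))])
    payer = to_perspective(result, 0.69, "payer")
    assert payer.net_cumulative()["France"] == pytest.approx(-69.0)


def test_empty_portfolio_zero_result(base_params):
    result = run_forecast([], base_params)
    assert set(result.countries) == set(base_params)
    assert (result.yearly() == 0).all().all()


def test_single_product_composition(base_params):
    product = offpatent("France", 5e6, 0.7, "2013-04")
    component, series = product_saving_series(product, base_params["France"])
    direct = aggregate([("France", component, series)])
    via_engine = run_forecast([product], base_params)
    pd.testing.assert_frame_equal(direct.yearly(), via_engine.yearly())


def test_engine_matches_bruteforce_oracle(base_params, random_portfolio_50):
    for perspective in ("society", "payer", "manufacturer"):
        result = run_forecast(random_portfolio_50, base_params, perspective=perspective)
        expected = oracle.run(random_portfolio_50, base_params, perspective=perspective)
        yearly = result.yearly()
        for country, years in expected.items():
            for year, comps in years.items():
                for component, value in comps.items():
                    got = yearly.loc[(country, year), component]
                    assert got == pytest.approx(value, rel=1e-9, abs=1e-6), (
                        country, year, component, perspective,
                    )


# --------------------------------------------------------------------------
# monotonicity and linearity


def _total_savings(portfolio, params):
    result = run_forecast(portfolio, params)
    cum = result.cumulative()
    return float((cum["generic_savings"] + cum["biosimilar_savings"]).sum())


def test_savings_monotone_in_market_parameters(base_params):
    portfolio = [offpatent("France", 1e6, 0.8, "2012-06")]
    base = _total_savings(portfolio, base_params)
    for path, value in [
        ("generic_retail.max_penetration", 1.0),
        ("generic_retail.price_reduction", 0.9),
        ("generic_retail.brand_price_impact", 0.5),
    ]:
        bumped = set_parameter(base_params, path, value, "France")
        assert _total_savings(portfolio, bumped) >= base


def test_innovation_cost_monotone_in_ttm(base_params):
    portfolio = [pipeline("France", "2012-06", 1e6)]
    costs = []
    for ttm in (0, 6, 12, 24):
        params = set_parameter(base_params, "brand_ttm_months", ttm, "France")
        costs.append(run_forecast(portfolio, params).net_cumulative()["France"])
    assert costs == sorted(costs, reverse=True)


def test_savings_linear_in_discount_without_brand_impact(base_params):
    portfolio = [offpatent("France", 1e6, 1.0, "2012-01")]
    params = set_parameter(base_params, "generic_retail.brand_price_impact", 0.0, "France")
    s_30 = _total_savings(portfolio, set_parameter(params, "generic_retail.price_reduction", 0.3, "France"))
    s_60 = _total_savings(portfolio, set_parameter(params, "generic_retail.price_reduction", 0.6, "France"))
    assert s_60 == pytest.approx(2 * s_30, rel=1e-12)


def test_discount_ratio_under_full_immediate_substitution(base_params):
    # 100% penetration, no ramp, no delay, no brand response: savings at an
    # 80% discount are exactly 1.6× those at 50%
    params = base_params
    for path, value in [
        ("generic_retail.max_penetration", 1.0),
        ("generic_retail.ramp_months", 0),
        ("generic_retail.time_to_market_days", 0),
        ("generic_retail.brand_price_impact", 0.0),
    ]:
        params = set_parameter(params, path, value, "France")
    portfolio = [offpatent("France", 1e6, 1.0, "2012-01")]
    s_50 = _total_savings(portfolio, set_parameter(params, "generic_retail.price_reduction", 0.5, "France"))
    s_80 = _total_savings(portfolio, set_parameter(params, "generic_retail.price_reduction", 0.8, "France"))
    assert s_80 / s_50 == pytest.approx(1.6, rel=1e-12)


# --------------------------------------------------------------------------
# horizon and I/O


def test_horizon_default_grid():
    assert DEFAULT_HORIZON.n_months == 60
    assert DEFAULT_HORIZON.years == (2012, 2013, 2014, 2015, 2016)
    assert DEFAULT_HORIZON.index("2012-01") == 0
    assert DEFAULT_HORIZON.index("2011-11") == -2
    with pytest.raises(ValueError):
        ForecastHorizon("2016-01", "2012-01")


def test_product_validation():
    with pytest.raises(ValueError):
        offpatent("France", -1.0, 0.5, "2012-01")
    with pytest.raises(ValueError):
        Product("x", "France", "small_molecule", "off_patent_candidate",
                1.0, 0.5, loe_month=None)
    with pytest.raises(ValueError):
        Product("x", "France", "gene_therapy", "pipeline", approval_month="2012-01")


def test_portfolio_csv_round_trip(tmp_path, small_portfolio):
    path = tmp_path / "portfolio.csv"
    write_portfolio_csv(small_portfolio, path)
    loaded = read_portfolio_csv(path)
    assert loaded == small_portfolio
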