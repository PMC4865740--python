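"""Naive month-by-month re-simulation, independent of the engine.

Plain Python loops with their own date arithmetic; used to cross-check the
vectorized engine on small portfolios.
"""

import math

N_MONTHS = 60
START_YEAR, START_MONTH = 2012, 1


def month_offset(month_str):
    year, month = (int(x) for x in month_str.split("-"))
    return (year - START_YEAR) * 12 + (month - START_MONTH)


def to_months(days):
    return int(math.floor(days / 30.44 + 0.5))


def chain_savings(annual_base, entry, discount, max_pen, ramp, brand_impact):
    values = []
    for m in range(N_MONTHS):
        if m < entry:
            values.append(0.0)
            continue
        if ramp == 0:
            p = max_pen
        else:
            p = max_pen * min(1.0, (m - entry) / ramp)
        values.append(annual_base / 12.0 * (p * discount + (1.0 - p) * brand_impact))
    return values


def offpatent_savings(product, params):
    loe = month_offset(product.loe_month)
    if product.molecule_class == "biologic":
        seg = params.biosimilar_retail
    else:
        seg = params.generic_retail
    retail = chain_savings(
        product.annual_sales_2011 * product.retail_share,
        loe + to_months(seg.time_to_market_days),
        seg.price_reduction,
        seg.max_penetration,
        seg.ramp_months,
        seg.brand_price_impact,
    )
    hosp = params.hospital
    hospital = chain_savings(
        product.annual_sales_2011 * (1.0 - product.retail_share),
        loe + to_months(hosp.time_to_market_days),
        hosp.price_reduction,
        hosp.max_penetration,
        hosp.ramp_months,
        hosp.brand_price_impact,
    )
    return [r + h for r, h in zip(retail, hospital)]


def pipeline_costs(product, params):
    launch = month_offset(product.approval_month) + params.brand_ttm_months
    values = []
    for m in range(N_MONTHS):
        if m < launch:
            values.append(0.0)
        else:
            frac = min(1.0, (m - launch + 1) / product.uptake_months)
            values.append(product.peak_annual_sales / 12.0 * frac)
    return values


def run(portfolio, params_by_country, perspective="society"):
    """country -> year -> component -> value (components positive, plus net)."""
    out = {}
    for product in portfolio:
        params = params_by_country[product.country]
        if product.lifecycle == "off_patent_candidate":
            monthly = offpatent_savings(product, params)
            component = (
                "biosimilar_savings"
                if product.molecule_class == "biologic"
                else "generic_savings"
            )
        else:
            monthly = pipeline_costs(product, params)
            component = "innovation_cost"
        years = out.setdefault(product.country, {})
        for m, value in enumerate(monthly):
            year = START_YEAR + m // 12
            comps = years.setdefault(
                year,
                {"generic_savings": 0.0, "biosimilar_savings": 0.0, "innovation_cost": 0.0},
            )
            comps[component] += value
    for country, years in out.items():
        rate = params_by_country[country].reimbursement_rate
        for year, comps in years.items():
            if perspective == "payer":
                for key in list(comps):
                    comps[key] *= rate
            elif perspective == "manufacturer":
                comps["generic_savings"] *= -1.0
                comps["biosimilar_savings"] *= -1.0
            comps["net"] = (
                comps["innovation_cost"]
                - comps["generic_savings"]
                - comps["biosimilar_savings"]
            )
    return out
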