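"""Published reference figures for the seven-country EU forecast.

The original study ran on a proprietary 2011 national sales extract, so its
country-level forecasts cannot be recomputed from raw data here. What *is*
independently checkable is the arithmetic that links its published figures:

* the yearly payer-perspective net impacts sum to the published cumulative,
* the coverage-expansion mechanics reproduce every published
  100%-reimbursement scenario figure from the base case, the reimbursement
  rate and the 2011 expansion cost,
* the hospital-shift biosimilar savings are exactly linear in the biosimilar
  discount, so the published 80%-discount column determines the 50% column.

:func:`verify_reference_tables` runs those checks through the package's own
operations. All figures are payer perspective, million € (constant 2011 €).
"""

from __future__ import annotations

from dataclasses import dataclass

from .policy_params import base_case_parameters
from .reporting import round_half_away
from .scenarios import biosimilar_hospital_shift, coverage_expansion_impact
from .synthetic import PortfolioConfig, calibrate_total, generate

__all__ = [
    "BASE_CASE_YEARLY_MEUR",
    "BASE_CASE_CUMULATIVE_MEUR",
    "COVERAGE_EXPANSION_2011_MEUR",
    "FULL_COVERAGE_CUMULATIVE_MEUR",
    "FULL_COVERAGE_DELTA_MEUR",
    "BIOSIMILAR_SHIFT_MEUR",
    "CheckResult",
    "verify_reference_tables",
    "calibrated_hospital_shift",
]

#: Base-case payer net budget impact per year 2012..2016, million €.
BASE_CASE_YEARLY_MEUR: dict[str, tuple[float, ...]] = {
    "France": (-451, -919, -1264, -1511, -1444),
    "Germany": (-402, -561, -413, -174, 719),
    "Greece": (-68, -134, -164, -221, -221),
    "Hungary": (-27, -31, -20, -7, 1),
    "Poland": (-4, 9, 6, 6, 24),
    "Portugal": (-7, -21, -47, -79, -89),
    "United Kingdom": (-920, -1831, -2210, -2309, -2097),
}

#: Base-case cumulative 2012–2016 payer net impact, million €.
BASE_CASE_CUMULATIVE_MEUR: dict[str, float] = {
    "France": -5589,
    "Germany": -831,
    "Greece": -808,
    "Hungary": -84,
    "Poland": 41,
    "Portugal": -243,
    "United Kingdom": -9367,
}

#: One-off 2011 cost of raising reimbursement to 100%, million €.
COVERAGE_EXPANSION_2011_MEUR: dict[str, float] = {
    "France": 11823,
    "Germany": 4017,
    "Greece": 1010,
    "Hungary": 669,
    "Poland": 1954,
    "Portugal": 741,
    "United Kingdom": 0,
}

#: Published cumulative payer impact under 100% reimbursement, million €.
FULL_COVERAGE_CUMULATIVE_MEUR: dict[str, float] = {
    "France": 3723,
    "Germany": 3094,
    "Greece": 0,
    "Hungary": 544,
    "Poland": 2020,
    "Portugal": 443,
    "United Kingdom": -9367,
}

#: Published delta of the 100%-reimbursement scenario vs base, million €.
FULL_COVERAGE_DELTA_MEUR: dict[str, float] = {
    "France": 9312,
    "Germany": 3925,
    "Greece": 808,
    "Hungary": 628,
    "Poland": 1979,
    "Portugal": 686,
    "United Kingdom": 0,
}

#: Hospital-shift biosimilar savings table, million €, payer perspective:
#: discount → country → (base-case savings, shifted savings, extra savings).
BIOSIMILAR_SHIFT_MEUR: dict[float, dict[str, tuple[float, float, float]]] = {
    0.8: {
        "France": (1127, 3317, 2190),
        "Germany": (1014, 4518, 3504),
        "Greece": (15, 225, 210),
        "Hungary": (19, 205, 186),
        "Poland": (125, 237, 112),
        "Portugal": (222, 286, 64),
        "United Kingdom": (2023, 2376, 353),
    },
    0.5: {
        "France": (712, 2073, 1361),
        "Germany": (667, 2824, 2157),
        "Greece": (15, 141, 126),
        "Hungary": (13, 128, 115),
        "Poland": (78, 148, 70),
        "Portugal": (139, 179, 40),
        "United Kingdom": (1268, 1485, 217),
    },
}


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str


def calibrated_hospital_shift(
    country: str, price_reduction: float, seed: int = 0, n_products: int = 20
) -> tuple[float, int]:
    """Hospital-shift savings after calibrating to the published 80% cell.

    Generates a seeded all-biologic portfolio for ``country``, rescales it so
    the hospital-shift run at an 80% discount reproduces the published
    80%-discount savings, then re-runs at ``price_reduction``. Returns the
    cumulative payer savings in million € (unrounded) and the portfolio size.
    The savings are exactly linear in the discount, so the result is
    seed-independent up to floating-point error.
    """
    params = base_case_parameters()
    config = PortfolioConfig(
        seed=seed,
        countries=[country],
        n_offpatent=n_products,
        n_pipeline=0,
        biologic_fraction=1.0,
        loe_window=("2012-01", "2015-12"),
    )
    portfolio = generate(config)
    raw_80 = biosimilar_hospital_shift(portfolio, params, 0.8)[country]
    target_80_eur = BIOSIMILAR_SHIFT_MEUR[0.8][country][1] * 1e6
    total = sum(p.annual_sales_2011 for p in portfolio)
    portfolio = calibrate_total(portfolio, {country: total * target_80_eur / raw_80})
    value = biosimilar_hospital_shift(portfolio, params, price_reduction)[country]
    return value / 1e6, len(portfolio)


def verify_reference_tables(seed: int = 0) -> list[CheckResult]:
    """Re-derive every published figure that follows from the others."""
    params = base_case_parameters()
    checks: list[CheckResult] = []

    for country, yearly in BASE_CASE_YEARLY_MEUR.items():
        total = sum(yearly)
        expected = BASE_CASE_CUMULATIVE_MEUR[country]
        checks.append(
            CheckResult(
                f"yearly-sum:{country}",
                total == expected,
                f"sum(yearly) = {total}, published cumulative = {expected}",
            )
        )

    for country, base in BASE_CASE_CUMULATIVE_MEUR.items():
        rate = params[country].reimbursement_rate
        cost = COVERAGE_EXPANSION_2011_MEUR[country]
        scenario, delta = coverage_expansion_impact(base, rate, cost)
        ok = (
            round_half_away(scenario) == FULL_COVERAGE_CUMULATIVE_MEUR[country]
            and round_half_away(delta) == FULL_COVERAGE_DELTA_MEUR[country]
        )
        checks.append(
            CheckResult(
                f"coverage-expansion:{country}",
                ok,
                f"computed {scenario:.1f} (delta {delta:.1f}), published "
                f"{FULL_COVERAGE_CUMULATIVE_MEUR[country]} "
                f"(delta {FULL_COVERAGE_DELTA_MEUR[country]})",
            )
        )

    for country in BIOSIMILAR_SHIFT_MEUR[0.8]:
        value, _ = calibrated_hospital_shift(country, 0.5, seed=seed)
        expected = BIOSIMILAR_SHIFT_MEUR[0.5][country][1]
        checks.append(
            CheckResult(
                f"hospital-shift-linearity:{country}",
                round_half_away(value) == expected,
                f"calibrated 80%→50% gives {value:.1f}, published {expected}",
            )
        )
    return checks
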