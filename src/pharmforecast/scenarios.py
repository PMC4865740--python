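"""Policy scenarios as transformations of the country parameter sets.

Nine built-in scenarios (plus the identity ``base``):

* ``s1`` — transplant the UK's market-access block (brand time to market,
  generic-retail and biosimilar-retail segments) to every country. The UK's
  100% reimbursement rate is deliberately *not* copied: the scenario probes
  market dynamics, not coverage levels.
* ``s2`` — Germany's brand time to market raised to 12 months.
* ``s3``/``s4`` — brand time to market 6 / 0 months everywhere.
* ``s5`` — reimbursement raised to 100% everywhere. On top of paying the full
  price of the 2012–2016 market movements, the payer picks up the share of
  the 2011 expenditure base previously borne by patients; that one-off
  coverage-expansion cost is added once to the cumulative figure.
* ``s6``/``s7`` — generic retail price reduction 75% / 85% everywhere.
* ``s8`` — generic retail penetration ceiling 100% everywhere.
* ``s9`` — all biosimilar volume routed through the hospital chain with
  immediate entry, full substitution and a chosen discount (50% or 80%);
  reported as the biosimilar-savings component in isolation, positive sign.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .engine import (
    DEFAULT_HORIZON,
    BudgetImpactResult,
    ForecastHorizon,
    Product,
    _chain_saving_series,
    run_forecast,
)
from .policy_params import PolicyParameterSet, SegmentParams, canonical_country

__all__ = [
    "Scenario",
    "builtin_scenarios",
    "get_scenario",
    "apply_scenario",
    "run_scenario",
    "coverage_expansion_cost",
    "coverage_expansion_impact",
    "biosimilar_hospital_shift",
    "compare",
]

_UK_POLICY_FIELDS = ("brand_ttm_months", "generic_retail", "biosimilar_retail")


@dataclass(frozen=True)
class Scenario:
    """A named patch over the parameter sets, plus optional special mechanics.

    ``param_patches`` maps a country name (or ``"all"``) to nested field
    overrides; ``copy_from`` replaces ``copy_fields`` of every country with
    the source country's values before patching. ``special`` marks the two
    mechanisms that are not expressible as parameter patches.
    """

    name: str
    description: str = ""
    param_patches: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)
    copy_from: str | None = None
    copy_fields: tuple[str, ...] = _UK_POLICY_FIELDS
    special: str | None = None  # coverage_expansion | biosimilar_hospital_shift
    special_args: Mapping[str, Any] = field(default_factory=dict)


def builtin_scenarios() -> dict[str, Scenario]:
    return {
        "base": Scenario("base", "reference forecast, parameters unchanged"),
        "s1": Scenario(
            "s1",
            "UK market-access policies applied to all countries",
            copy_from="United Kingdom",
        ),
        "s2": Scenario(
            "s2",
            "brand time to market raised to 12 months for Germany",
            param_patches={"Germany": {"brand_ttm_months": 12}},
        ),
        "s3": Scenario(
            "s3",
            "brand time to market 6 months for all countries",
            param_patches={"all": {"brand_ttm_months": 6}},
        ),
        "s4": Scenario(
            "s4",
            "brand time to market 0 months for all countries",
            param_patches={"all": {"brand_ttm_months": 0}},
        ),
        "s5": Scenario(
            "s5",
            "reimbursement rate raised to 100% for all countries",
            param_patches={"all": {"reimbursement_rate": 1.0}},
            special="coverage_expansion",
        ),
        "s6": Scenario(
            "s6",
            "generic retail price reduction 75% for all countries",
            param_patches={"all": {"generic_retail": {"price_reduction": 0.75}}},
        ),
        "s7": Scenario(
            "s7",
            "generic retail price reduction 85% for all countries",
            param_patches={"all": {"generic_retail": {"price_reduction": 0.85}}},
        ),
        "s8": Scenario(
            "s8",
            "generic retail penetration 100% for all countries",
            param_patches={"all": {"generic_retail": {"max_penetration": 1.0}}},
        ),
        "s9": Scenario(
            "s9",
            "all biosimilars distributed through the hospital chain",
            special="biosimilar_hospital_shift",
            special_args={"price_reduction": 0.8},
        ),
    }


def get_scenario(name: str) -> Scenario:
    scenarios = builtin_scenarios()
    if name not in scenarios:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(scenarios)}"
        )
    return scenarios[name]


def _deep_update(target: dict, patch: Mapping, where: str) -> None:
    for key, value in patch.items():
        if key not in target:
            raise ValueError(f"{where}: unknown parameter field {key!r}")
        if isinstance(value, Mapping):
            if not isinstance(target[key], dict):
                raise ValueError(f"{where}: field {key!r} is not a nested block")
            _deep_update(target[key], value, f"{where}.{key}")
        else:
            target[key] = value


def apply_scenario(
    params_by_country: Mapping[str, PolicyParameterSet], scenario: Scenario
) -> dict[str, PolicyParameterSet]:
    """Return patched parameter sets; the inputs are never mutated.

    Patched values are re-validated, so a patch cannot push a parameter out
    of its legal range unnoticed. Application is idempotent.
    """
    source = None
    if scenario.copy_from is not None:
        source = params_by_country[canonical_country(scenario.copy_from)]
    out: dict[str, PolicyParameterSet] = {}
    for country, params in params_by_country.items():
        data = params.model_dump()
        if source is not None:
            src = source.model_dump()
            for fname in scenario.copy_fields:
                data[fname] = copy.deepcopy(src[fname])
        for scope in ("all", country):
            patch = scenario.param_patches.get(scope)
            if patch:
                _deep_update(data, patch, f"{scenario.name}:{country}")
        out[country] = PolicyParameterSet.model_validate(data)
    return out


def run_scenario(
    portfolio: Iterable[Product],
    params_by_country: Mapping[str, PolicyParameterSet],
    scenario: Scenario,
    horizon: ForecastHorizon = DEFAULT_HORIZON,
    perspective: str = "payer",
) -> BudgetImpactResult:
    """Run the forecast under a scenario's parameter patches.

    The ``s9`` hospital-shift mechanism replaces the market model and is not
    expressible as a patched forecast; use :func:`biosimilar_hospital_shift`.
    The one-off 2011 coverage-expansion cost of ``s5`` is likewise layered on
    by :func:`coverage_expansion_impact` at reporting time.
    """
    if scenario.special == "biosimilar_hospital_shift":
        raise ValueError("scenario s9 is evaluated with biosimilar_hospital_shift()")
    patched = apply_scenario(params_by_country, scenario)
    return run_forecast(list(portfolio), patched, horizon, perspective)


# --------------------------------------------------------------------------
# Special mechanisms


def coverage_expansion_cost(total_sales_2011: float, reimbursement_rate: float) -> float:
    """One-off 2011 cost of extending coverage to 100%.

    The share of the 2011 expenditure base not currently reimbursed,
    (1 − rate) × total 2011 sales value, lands on the payer when coverage
    becomes universal.
    """
    if not 0.0 < reimbursement_rate <= 1.0:
        raise ValueError("reimbursement_rate must be in (0, 1]")
    return (1.0 - reimbursement_rate) * total_sales_2011


def coverage_expansion_impact(
    base_cumulative_payer: float,
    reimbursement_rate: float,
    expansion_cost_2011: float,
) -> tuple[float, float]:
    """Cumulative payer impact when reimbursement is raised to 100%.

    Every market movement previously reimbursed at ``rate`` is now borne in
    full, so the cumulative payer impact rescales to
    ``base / rate``; the one-off 2011 coverage-expansion cost is then added
    once. Returns ``(scenario_cumulative, delta_vs_base)``.
    """
    if not 0.0 < reimbursement_rate <= 1.0:
        raise ValueError("reimbursement_rate must be in (0, 1]")
    scenario_cumulative = base_cumulative_payer / reimbursement_rate + expansion_cost_2011
    return scenario_cumulative, scenario_cumulative - base_cumulative_payer


def biosimilar_hospital_shift(
    portfolio: Iterable[Product],
    params_by_country: Mapping[str, PolicyParameterSet],
    price_reduction: float,
    horizon: ForecastHorizon = DEFAULT_HORIZON,
) -> pd.Series:
    """Cumulative biosimilar savings when all biosimilars go hospital-only.

    Every off-patent biologic's full sales value is routed through the
    hospital chain with tender conditions: immediate entry at loss of
    exclusivity, 100% substitution, no ramp, no originator price response,
    and the given biosimilar discount. Returns payer-perspective cumulative
    savings per country, positive sign.
    """
    if not 0.0 <= price_reduction <= 1.0:
        raise ValueError("price_reduction must be in [0, 1]")
    shift_segment = SegmentParams(
        time_to_market_days=0,
        price_reduction=price_reduction,
        max_penetration=1.0,
        ramp_months=0,
        brand_price_impact=0.0,
    )
    products = list(portfolio)
    missing = {p.country for p in products} - set(params_by_country)
    if missing:
        raise KeyError(f"no parameter set for {sorted(missing)}")
    totals: dict[str, float] = {p.country: 0.0 for p in products}
    for product in products:
        if product.lifecycle != "off_patent_candidate":
            continue
        if product.molecule_class != "biologic":
            continue
        series = _chain_saving_series(
            product.annual_sales_2011,
            horizon.index(product.loe_month),
            shift_segment,
            horizon,
        )
        rate = params_by_country[product.country].reimbursement_rate
        totals[product.country] += float(series.sum()) * rate
    return pd.Series(totals, dtype=float).sort_index().rename("biosimilar_savings")


def compare(base, scenario_result) -> pd.DataFrame:
    """Per-country base vs scenario cumulative figures and their delta.

    Accepts two :class:`BudgetImpactResult` objects (compared on cumulative
    net) or two per-country Series (e.g. hospital-shift savings, where the
    delta is the extra savings). Countries must match.
    """
    if isinstance(base, BudgetImpactResult):
        base_series = base.net_cumulative()
    else:
        base_series = pd.Series(base, dtype=float)
    if isinstance(scenario_result, BudgetImpactResult):
        scen_series = scenario_result.net_cumulative()
    else:
        scen_series = pd.Series(scenario_result, dtype=float)
    if set(base_series.index) != set(scen_series.index):
        raise ValueError("base and scenario cover different countries")
    frame = pd.DataFrame(
        {
            "base": base_series,
            "scenario": scen_series.reindex(base_series.index),
        }
    )
    frame["delta"] = frame["scenario"] - frame["base"]
    frame.index.name = "country"
    return frame
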