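"""Monthly budget-impact engine for the 2012–2016 forecast horizon.

The model has two halves:

* **Off-patent dynamics.** After a product loses exclusivity, copies
  (generics for small molecules, biosimilars for biologics) enter each
  distribution segment after that segment's time to market, capture a
  linearly-ramping volume share up to a penetration ceiling, and sell at a
  discount to the originator price; the originator cuts its own price by a
  step at copy entry. With total volume held constant, the monthly saving
  against the no-loss-of-exclusivity counterfactual is

      S/12 · [ p(t)·d + (1 − p(t))·b·1(entered) ]

  where S is the product's pre-expiry annual sales value, p(t) the copy
  volume share, d the copy price discount and b the originator price cut.

* **Innovative entries.** A pipeline product launches a fixed number of
  months after marketing authorization (the country's brand time to market)
  and its monthly sales ramp linearly to peak over its uptake period; these
  sales are additional cost.

Results are aggregated to calendar years and a 2012–2016 cumulative, per
country and component, and can be restated from the society perspective to
the public payer (scaled by the reimbursement rate) or the manufacturer
(sign-flipped savings). All values are in constant 2011 euros; no
discounting is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .policy_params import PolicyParameterSet, SegmentParams

__all__ = [
    "COMPONENTS",
    "PERSPECTIVES",
    "ForecastHorizon",
    "DEFAULT_HORIZON",
    "Product",
    "BudgetImpactResult",
    "days_to_months",
    "penetration",
    "offpatent_monthly_saving",
    "product_saving_series",
    "innovation_cost_series",
    "aggregate",
    "to_perspective",
    "run_forecast",
    "read_portfolio_csv",
    "write_portfolio_csv",
]

#: Expenditure components; savings are stored positive, the derived ``net``
#: equals innovation_cost − generic_savings − biosimilar_savings, so a
#: negative net is an overall saving.
COMPONENTS = ("generic_savings", "biosimilar_savings", "innovation_cost")
PERSPECTIVES = ("payer", "society", "manufacturer")

MOLECULE_CLASSES = ("small_molecule", "biologic")
LIFECYCLES = ("off_patent_candidate", "pipeline")

_DAYS_PER_MONTH = 30.44  # mean Gregorian month length


def days_to_months(days: float) -> int:
    """Convert a day-denominated delay to whole months (nearest)."""
    if days < 0:
        raise ValueError("negative delay")
    return int(math.floor(days / _DAYS_PER_MONTH + 0.5))


def _as_period(month) -> pd.Period:
    return month if isinstance(month, pd.Period) else pd.Period(month, freq="M")


@dataclass(frozen=True)
class ForecastHorizon:
    """Monthly forecast grid, by default January 2012 – December 2016."""

    start: pd.Period = pd.Period("2012-01", freq="M")
    end: pd.Period = pd.Period("2016-12", freq="M")

    def __post_init__(self):
        object.__setattr__(self, "start", _as_period(self.start))
        object.__setattr__(self, "end", _as_period(self.end))
        if self.end < self.start:
            raise ValueError("horizon end precedes start")

    @property
    def n_months(self) -> int:
        return (self.end - self.start).n + 1

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start.year, self.end.year + 1))

    def index(self, month) -> int:
        """Month offset from the horizon start (may be negative or beyond)."""
        return (_as_period(month) - self.start).n

    def year_index(self) -> np.ndarray:
        """Calendar year of each monthly step."""
        return np.array(
            [(self.start + k).year for k in range(self.n_months)], dtype=int
        )


DEFAULT_HORIZON = ForecastHorizon()


@dataclass(frozen=True)
class Product:
    """One drug in the portfolio.

    Off-patent candidates carry a 2011 sales base, a retail/hospital value
    split and a loss-of-exclusivity month; pipeline entrants carry an
    approval month, forecast peak annual sales and an uptake period.
    """

    product_id: str
    country: str
    molecule_class: str
    lifecycle: str
    annual_sales_2011: float = 0.0
    retail_share: float = 0.0
    loe_month: str | None = None
    approval_month: str | None = None
    peak_annual_sales: float = 0.0
    uptake_months: int = 12

    def __post_init__(self):
        if self.molecule_class not in MOLECULE_CLASSES:
            raise ValueError(f"molecule_class must be one of {MOLECULE_CLASSES}")
        if self.lifecycle not in LIFECYCLES:
            raise ValueError(f"lifecycle must be one of {LIFECYCLES}")
        if self.annual_sales_2011 < 0 or self.peak_annual_sales < 0:
            raise ValueError("sales values must be nonnegative")
        if not 0.0 <= self.retail_share <= 1.0:
            raise ValueError("retail_share must be in [0, 1]")
        if self.lifecycle == "off_patent_candidate":
            if self.loe_month is None:
                raise ValueError("off-patent candidate needs loe_month")
            if self.approval_month is not None:
                raise ValueError("off-patent candidate must not set approval_month")
        else:
            if self.approval_month is None:
                raise ValueError("pipeline product needs approval_month")
            if self.loe_month is not None:
                raise ValueError("pipeline product must not set loe_month")
            if self.annual_sales_2011 != 0.0:
                raise ValueError("pipeline product has no 2011 sales base")
            if self.uptake_months < 1:
                raise ValueError("uptake_months must be positive")

    def scaled(self, factor: float) -> "Product":
        """Return a copy with all sales values multiplied by ``factor``."""
        return Product(
            product_id=self.product_id,
            country=self.country,
            molecule_class=self.molecule_class,
            lifecycle=self.lifecycle,
            annual_sales_2011=self.annual_sales_2011 * factor,
            retail_share=self.retail_share,
            loe_month=self.loe_month,
            approval_month=self.approval_month,
            peak_annual_sales=self.peak_annual_sales * factor,
            uptake_months=self.uptake_months,
        )


# --------------------------------------------------------------------------
# Elementary dynamics


def penetration(
    month_index: int, entry_month: int, max_penetration: float, ramp_months: int
) -> float:
    """Copy volume share at a given month.

    Zero before entry; with a zero ramp the share jumps to the ceiling at the
    entry month, otherwise it climbs linearly from 0 at entry to the ceiling
    ``ramp_months`` later and stays there.
    """
    if ramp_months < 0:
        raise ValueError("ramp_months must be nonnegative")
    if month_index < entry_month:
        return 0.0
    if ramp_months == 0:
        return max_penetration
    return max_penetration * min(1.0, (month_index - entry_month) / ramp_months)


def offpatent_monthly_saving(
    monthly_sales_base: float,
    p: float,
    price_reduction: float,
    brand_price_impact: float,
    entered: bool,
) -> float:
    """Monthly saving vs the no-expiry counterfactual, constant total volume.

    The copy share ``p`` of the volume is bought at a discount
    ``price_reduction``; the remaining originator share is bought at a price
    cut ``brand_price_impact`` once copies have entered.
    """
    erosion = brand_price_impact if entered else 0.0
    return monthly_sales_base * (p * price_reduction + (1.0 - p) * erosion)


def _chain_saving_series(
    annual_base: float, entry: int, seg: SegmentParams, horizon: ForecastHorizon
) -> np.ndarray:
    """Vectorized monthly savings for one distribution chain."""
    n = horizon.n_months
    m = np.arange(n)
    entered = m >= entry
    if seg.ramp_months == 0:
        p = np.where(entered, seg.max_penetration, 0.0)
    else:
        p = np.where(
            entered,
            seg.max_penetration * np.clip((m - entry) / seg.ramp_months, 0.0, 1.0),
            0.0,
        )
    erosion = np.where(entered, seg.brand_price_impact, 0.0)
    return (annual_base / 12.0) * (p * seg.price_reduction + (1.0 - p) * erosion)


def product_saving_series(
    product: Product,
    params: PolicyParameterSet,
    horizon: ForecastHorizon = DEFAULT_HORIZON,
) -> tuple[str, np.ndarray]:
    """Monthly society-perspective savings for one off-patent candidate.

    The sales base is split by ``retail_share``; the retail part follows the
    generic-retail or biosimilar-retail segment according to molecule class,
    the hospital part follows the hospital segment. Returns the component tag
    (``generic_savings`` or ``biosimilar_savings``) and the series.
    """
    if product.lifecycle != "off_patent_candidate":
        raise ValueError("product_saving_series requires an off-patent candidate")
    loe = horizon.index(product.loe_month)
    if product.molecule_class == "biologic":
        retail_seg, component = params.biosimilar_retail, "biosimilar_savings"
    else:
        retail_seg, component = params.generic_retail, "generic_savings"
    series = _chain_saving_series(
        product.annual_sales_2011 * product.retail_share,
        loe + days_to_months(retail_seg.time_to_market_days),
        retail_seg,
        horizon,
    )
    series += _chain_saving_series(
        product.annual_sales_2011 * (1.0 - product.retail_share),
        loe + days_to_months(params.hospital.time_to_market_days),
        params.hospital,
        horizon,
    )
    return component, series


def innovation_cost_series(
    product: Product,
    params: PolicyParameterSet,
    horizon: ForecastHorizon = DEFAULT_HORIZON,
) -> tuple[str, np.ndarray]:
    """Monthly additional cost of one pipeline entrant.

    Launch occurs ``brand_ttm_months`` after approval; monthly sales climb
    linearly over the uptake period — the k-th month on the market books
    k/uptake of the peak monthly value, capped at peak — with no
    post-horizon decay.
    """
    if product.lifecycle != "pipeline":
        raise ValueError("innovation_cost_series requires a pipeline product")
    launch = horizon.index(product.approval_month) + params.brand_ttm_months
    m = np.arange(horizon.n_months)
    on_market = m >= launch
    ramp = np.clip((m - launch + 1) / product.uptake_months, 0.0, 1.0)
    series = (product.peak_annual_sales / 12.0) * ramp * on_market
    return "innovation_cost", series


# --------------------------------------------------------------------------
# Aggregation and perspectives


class BudgetImpactResult:
    """Country × year × component expenditure deltas, one perspective.

    Components are stored positive; ``net`` is derived as
    innovation_cost − generic_savings − biosimilar_savings, so a negative
    net means the portfolio saves money overall.
    """

    def __init__(self, yearly: pd.DataFrame, perspective: str = "society"):
        if perspective not in PERSPECTIVES:
            raise ValueError(f"perspective must be one of {PERSPECTIVES}")
        expected = list(COMPONENTS)
        if list(yearly.columns) != expected:
            yearly = yearly.reindex(columns=expected)
        self._yearly = yearly.sort_index()
        self.perspective = perspective

    @classmethod
    def zeros(
        cls,
        countries: Sequence[str],
        horizon: ForecastHorizon = DEFAULT_HORIZON,
        perspective: str = "society",
    ) -> "BudgetImpactResult":
        idx = pd.MultiIndex.from_product(
            [sorted(countries), horizon.years], names=["country", "year"]
        )
        frame = pd.DataFrame(0.0, index=idx, columns=list(COMPONENTS))
        return cls(frame, perspective)

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(self._yearly.index.get_level_values("country").unique())

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self._yearly.index.get_level_values("year").unique())

    def yearly(self) -> pd.DataFrame:
        """Yearly values with the derived ``net`` column."""
        frame = self._yearly.copy()
        frame["net"] = (
            frame["innovation_cost"]
            - frame["generic_savings"]
            - frame["biosimilar_savings"]
        )
        return frame

    def cumulative(self) -> pd.DataFrame:
        """Per-country totals over the whole horizon, with ``net``."""
        return self.yearly().groupby(level="country").sum()

    def net_cumulative(self) -> pd.Series:
        return self.cumulative()["net"]

    def component_cumulative(self, component: str) -> pd.Series:
        return self.cumulative()[component]

    def tidy(self) -> pd.DataFrame:
        """Long-format frame including cumulative rows (year label spans)."""
        yearly = self.yearly()
        span = f"{min(self.years)}-{max(self.years)}"
        rows = yearly.reset_index().melt(
            id_vars=["country", "year"], var_name="component", value_name="value_eur"
        )
        cum = self.cumulative().reset_index().melt(
            id_vars=["country"], var_name="component", value_name="value_eur"
        )
        cum.insert(1, "year", span)
        out = pd.concat([rows, cum], ignore_index=True)
        out.insert(3, "perspective", self.perspective)
        return out

    def _with_frame(self, frame: pd.DataFrame, perspective: str) -> "BudgetImpactResult":
        return BudgetImpactResult(frame, perspective)


def aggregate(
    series_by_product_and_component: Iterable[tuple[str, str, np.ndarray]],
    horizon: ForecastHorizon = DEFAULT_HORIZON,
    countries: Sequence[str] | None = None,
) -> BudgetImpactResult:
    """Sum tagged monthly series into a society-perspective yearly result.

    Input items are ``(country, component, monthly_series)``; all series must
    share the horizon's monthly grid.
    """
    items = list(series_by_product_and_component)
    seen = {c for c, _, _ in items}
    all_countries = sorted(seen | set(countries or ()))
    result = BudgetImpactResult.zeros(all_countries, horizon)
    frame = result._yearly
    year_of_month = horizon.year_index()
    for country, component, series in items:
        series = np.asarray(series, dtype=float)
        if series.shape != (horizon.n_months,):
            raise ValueError("series length does not match the horizon")
        if component not in COMPONENTS:
            raise ValueError(f"unknown component {component!r}")
        sums = pd.Series(series).groupby(year_of_month).sum()
        for year, value in sums.items():
            frame.loc[(country, int(year)), component] += value
    return result


_MANUFACTURER_SIGN = {
    "generic_savings": -1.0,  # copy substitution is industry revenue loss
    "biosimilar_savings": -1.0,
    "innovation_cost": 1.0,  # new launches are industry revenue gain
}


def to_perspective(
    result: BudgetImpactResult,
    reimbursement_rate: float | Mapping[str, float],
    perspective: str,
) -> BudgetImpactResult:
    """Restate a society-perspective result under another accounting view.

    Payer values are the society values scaled by the reimbursement rate
    (uniformly across components and chains); manufacturer values flip the
    sign of the savings components and keep innovation as revenue gain.
    """
    if result.perspective != "society":
        raise ValueError("perspective conversion starts from the society view")
    if perspective == "society":
        return result._with_frame(result._yearly.copy(), "society")
    if perspective == "payer":
        frame = result._yearly.copy()
        if isinstance(reimbursement_rate, Mapping):
            countries = frame.index.get_level_values("country")
            missing = set(countries) - set(reimbursement_rate)
            if missing:
                raise KeyError(f"no reimbursement rate for {sorted(missing)}")
            rates = np.array([reimbursement_rate[c] for c in countries])
        else:
            rates = float(reimbursement_rate)
        frame = frame.mul(rates, axis=0)
        return result._with_frame(frame, "payer")
    if perspective == "manufacturer":
        frame = result._yearly.copy()
        for component, sign in _MANUFACTURER_SIGN.items():
            frame[component] *= sign
        return result._with_frame(frame, "manufacturer")
    raise ValueError(f"perspective must be one of {PERSPECTIVES}")


def run_forecast(
    portfolio: Iterable[Product],
    params_by_country: Mapping[str, PolicyParameterSet],
    horizon: ForecastHorizon = DEFAULT_HORIZON,
    perspective: str = "society",
) -> BudgetImpactResult:
    """Forecast the full portfolio: per-product series, aggregation, view.

    Deterministic given inputs. Every product's country must have a
    parameter set; an empty portfolio yields a zero result over the
    parameter sets' countries.
    """
    products = list(portfolio)
    missing = {p.country for p in products} - set(params_by_country)
    if missing:
        raise KeyError(f"no parameter set for {sorted(missing)}")
    tagged = []
    for product in products:
        params = params_by_country[product.country]
        if product.lifecycle == "off_patent_candidate":
            component, series = product_saving_series(product, params, horizon)
        else:
            component, series = innovation_cost_series(product, params, horizon)
        tagged.append((product.country, component, series))
    countries = {p.country for p in products} or set(params_by_country)
    society = aggregate(tagged, horizon, countries=sorted(countries))
    rates = {c: params_by_country[c].reimbursement_rate for c in countries}
    return to_perspective(society, rates, perspective)


# --------------------------------------------------------------------------
# Portfolio CSV schema

_CSV_COLUMNS = [
    "product_id",
    "country",
    "molecule_class",
    "lifecycle",
    "annual_sales_2011_eur",
    "retail_share",
    "loe_month",
    "approval_month",
    "peak_annual_sales_eur",
    "uptake_months",
]


def write_portfolio_csv(products: Iterable[Product], path: str | Path) -> None:
    rows = []
    for p in products:
        rows.append(
            {
                "product_id": p.product_id,
                "country": p.country,
                "molecule_class": p.molecule_class,
                "lifecycle": p.lifecycle,
                "annual_sales_2011_eur": p.annual_sales_2011,
                "retail_share": p.retail_share,
                "loe_month": p.loe_month or "",
                "approval_month": p.approval_month or "",
                "peak_annual_sales_eur": p.peak_annual_sales,
                "uptake_months": p.uptake_months,
            }
        )
    # %.17g keeps the full double precision so a round trip is lossless
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_portfolio_csv(path: str | Path) -> list[Product]:
    frame = pd.read_csv(
        path,
        dtype={"loe_month": "string", "approval_month": "string"},
        float_precision="round_trip",
    )
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"portfolio CSV missing columns {sorted(missing)}")
    products = []
    for row in frame.itertuples(index=False):
        loe = row.loe_month if pd.notna(row.loe_month) and row.loe_month else None
        approval = (
            row.approval_month
            if pd.notna(row.approval_month) and row.approval_month
            else None
        )
        products.append(
            Product(
                product_id=str(row.product_id),
                country=str(row.country),
                molecule_class=str(row.molecule_class),
                lifecycle=str(row.lifecycle),
                annual_sales_2011=float(row.annual_sales_2011_eur),
                retail_share=float(row.retail_share),
                loe_month=loe,
                approval_month=approval,
                peak_annual_sales=float(row.peak_annual_sales_eur),
                uptake_months=int(row.uptake_months),
            )
        )
    return products
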