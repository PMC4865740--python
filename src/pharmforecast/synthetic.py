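"""Seeded synthetic drug portfolios with the structure the engine expects.

Real national sales extracts are proprietary, so testing and worked examples
run on generated portfolios: per country, a set of off-patent candidates
(2011 sales value, retail/hospital value split, molecule class, loss-of-
exclusivity month) and a set of pipeline entrants (approval month, forecast
peak sales, uptake period). Sales magnitudes are log-normal — pharmaceutical
market value is dominated by a small number of blockbusters — and the
retail/hospital split is Beta-distributed. Loss-of-exclusivity dates may
precede the forecast horizon, so portfolios exercise ramps already in
progress at the start of 2012.

Generation draws from a single seeded stream in a fixed country → product →
field order, so a portfolio is fully reproducible from its config.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import Product
from .policy_params import COUNTRIES

__all__ = ["PortfolioConfig", "generate", "calibrate_total"]


class PortfolioConfig(BaseModel):
    """Distributional knobs for the generator.

    Defaults give each country 40 off-patent candidates (median sales
    ~€40 m/yr, heavy upper tail), a quarter of them biologics, plus 15
    pipeline entrants; expiries are spread over 2010–2016 so savings build
    up through the horizon the way a real expiry calendar would.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    countries: Sequence[str] = COUNTRIES
    n_offpatent: int = Field(default=40, ge=0)
    n_pipeline: int = Field(default=15, ge=0)
    biologic_fraction: float = Field(default=0.25, ge=0.0, le=1.0)
    #: log-normal parameters of the 2011 annual sales value, €
    sales_lognormal_mu: float = math.log(40e6)
    sales_lognormal_sigma: float = Field(default=1.0, gt=0.0)
    #: Beta(a, b) for the retail value share (mean a/(a+b))
    retail_share_beta: tuple[float, float] = (4.0, 2.0)
    loe_window: tuple[str, str] = ("2010-01", "2016-12")
    approval_window: tuple[str, str] = ("2012-01", "2016-06")
    peak_sales_lognormal_mu: float = math.log(60e6)
    peak_sales_lognormal_sigma: float = Field(default=0.8, gt=0.0)
    uptake_months_range: tuple[int, int] = (12, 48)
    #: optional per-country calibration target for total 2011 sales, €
    target_total_2011_sales: dict[str, float] | None = None

    @model_validator(mode="after")
    def _check_windows(self):
        for name in ("loe_window", "approval_window"):
            lo, hi = (pd.Period(m, freq="M") for m in getattr(self, name))
            if hi < lo:
                raise ValueError(f"{name} is not well-ordered")
        lo, hi = self.uptake_months_range
        if lo < 1 or hi < lo:
            raise ValueError("uptake_months_range must be a positive ordered range")
        a, b = self.retail_share_beta
        if a <= 0 or b <= 0:
            raise ValueError("retail_share_beta parameters must be positive")
        return self


def _month_range(window: tuple[str, str]) -> list[str]:
    lo, hi = (pd.Period(m, freq="M") for m in window)
    return [str(lo + k) for k in range((hi - lo).n + 1)]


def generate(config: PortfolioConfig) -> list[Product]:
    """Draw a portfolio; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    months_loe = _month_range(config.loe_window)
    months_approval = _month_range(config.approval_window)
    products: list[Product] = []
    for country in config.countries:
        for i in range(config.n_offpatent):
            sales = float(
                rng.lognormal(config.sales_lognormal_mu, config.sales_lognormal_sigma)
            )
            share = float(rng.beta(*config.retail_share_beta))
            is_biologic = bool(rng.random() < config.biologic_fraction)
            loe = months_loe[int(rng.integers(len(months_loe)))]
            products.append(
                Product(
                    product_id=f"{country[:3].upper()}-OFF-{i:03d}",
                    country=country,
                    molecule_class="biologic" if is_biologic else "small_molecule",
                    lifecycle="off_patent_candidate",
                    annual_sales_2011=sales,
                    retail_share=share,
                    loe_month=loe,
                )
            )
        for i in range(config.n_pipeline):
            peak = float(
                rng.lognormal(
                    config.peak_sales_lognormal_mu, config.peak_sales_lognormal_sigma
                )
            )
            is_biologic = bool(rng.random() < config.biologic_fraction)
            approval = months_approval[int(rng.integers(len(months_approval)))]
            lo, hi = config.uptake_months_range
            uptake = int(rng.integers(lo, hi + 1))
            products.append(
                Product(
                    product_id=f"{country[:3].upper()}-PIP-{i:03d}",
                    country=country,
                    molecule_class="biologic" if is_biologic else "small_molecule",
                    lifecycle="pipeline",
                    approval_month=approval,
                    peak_annual_sales=peak,
                    uptake_months=uptake,
                )
            )
    if config.target_total_2011_sales:
        products = calibrate_total(products, config.target_total_2011_sales)
    return products


def calibrate_total(
    portfolio: Iterable[Product], target_total: float | Mapping[str, float]
) -> list[Product]:
    """Rescale each country's sales so its 2011 total hits the target.

    A scalar target applies to every country. Both the 2011 sales base and
    pipeline peak sales are scaled, so every euro-denominated engine output
    scales by the same factor (the engine is homogeneous in the sales base).
    Raises on a country with zero 2011 sales.
    """
    products = list(portfolio)
    totals: dict[str, float] = {}
    for p in products:
        totals[p.country] = totals.get(p.country, 0.0) + p.annual_sales_2011
    if isinstance(target_total, Mapping):
        targets = dict(target_total)
    else:
        targets = {country: float(target_total) for country in totals}
    factors: dict[str, float] = {}
    for country, target in targets.items():
        if country not in totals:
            raise KeyError(f"no products for country {country!r}")
        if totals[country] <= 0.0:
            raise ValueError(f"{country}: zero 2011 sales, cannot calibrate")
        factors[country] = target / totals[country]
    return [
        p.scaled(factors[p.country]) if p.country in factors else p for p in products
    ]
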