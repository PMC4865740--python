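"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs the forecast at the two bounds of a single
parameter and reports the swing of the cumulative payer-perspective net
impact; a tornado table ranks several parameters by swing. Probabilistic
analysis draws parameter values from per-parameter distributions
(independently across parameters — no correlation structure is imposed),
re-runs the forecast per draw, and summarizes the per-country cumulative
net impact as mean and 2.5/50/97.5 percentiles.

The shipped default specification puts ±20% relative uniform ranges
(truncated to [0, 1]) on the retail price-reduction and penetration
fractions of every country, which is an illustrative envelope rather than
an elicited one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import (
    DEFAULT_HORIZON,
    ForecastHorizon,
    Product,
    run_forecast,
)
from .policy_params import PolicyParameterSet
from .scenarios import Scenario, apply_scenario

__all__ = [
    "ParameterDistributionSpec",
    "set_parameter",
    "one_way",
    "tornado",
    "probabilistic",
    "default_specs",
]


def _nest(path: str, value) -> dict:
    """Turn ``"generic_retail.price_reduction"`` into a nested patch dict."""
    parts = path.split(".")
    patch: dict = {parts[-1]: value}
    for part in reversed(parts[:-1]):
        patch = {part: patch}
    return patch


def set_parameter(
    params_by_country: Mapping[str, PolicyParameterSet],
    path: str,
    value,
    country: str = "all",
) -> dict[str, PolicyParameterSet]:
    """Return parameter sets with one field overridden (validated)."""
    scenario = Scenario(
        name=f"set:{country}:{path}", param_patches={country: _nest(path, value)}
    )
    return apply_scenario(params_by_country, scenario)


@dataclass(frozen=True)
class ParameterDistributionSpec:
    """Sampling distribution for one parameter of one (or every) country.

    ``kind`` is one of ``fixed_range``/``uniform`` (uniform over
    [low, high]), ``beta`` (Beta(alpha, beta) rescaled to [low, high]), or
    ``triangular`` (low, mode, high). A degenerate spec (low == high) is a
    point mass. Support must lie within the parameter's legal range; the
    violation surfaces as a validation error when the draw is applied.
    """

    path: str
    country: str = "all"
    kind: str = "uniform"
    low: float = 0.0
    high: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    mode: float | None = None

    def __post_init__(self):
        if self.kind not in ("fixed_range", "uniform", "beta", "triangular"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.high < self.low:
            raise ValueError("high < low")

    def sample(self, rng: np.random.Generator) -> float:
        if self.low == self.high:
            return self.low
        if self.kind in ("fixed_range", "uniform"):
            return float(rng.uniform(self.low, self.high))
        if self.kind == "beta":
            u = float(rng.beta(self.alpha, self.beta))
            return self.low + u * (self.high - self.low)
        mode = self.mode if self.mode is not None else 0.5 * (self.low + self.high)
        return float(rng.triangular(self.low, mode, self.high))


def _net_cumulative(
    portfolio: Sequence[Product],
    params: Mapping[str, PolicyParameterSet],
    horizon: ForecastHorizon,
) -> pd.Series:
    return run_forecast(portfolio, params, horizon, perspective="payer").net_cumulative()


def one_way(
    portfolio: Iterable[Product],
    params_by_country: Mapping[str, PolicyParameterSet],
    parameter_path: str,
    low: float,
    high: float,
    country: str = "all",
    horizon: ForecastHorizon = DEFAULT_HORIZON,
) -> tuple[float, float, float]:
    """Re-run the forecast at both bounds of one parameter.

    Returns ``(low_result, high_result, swing)`` where the results are the
    cumulative payer-perspective net impact summed over countries and
    ``swing = |high_result − low_result|``.
    """
    if low > high:
        raise ValueError("low > high")
    products = list(portfolio)
    low_val = float(
        _net_cumulative(
            products, set_parameter(params_by_country, parameter_path, low, country),
            horizon,
        ).sum()
    )
    high_val = float(
        _net_cumulative(
            products, set_parameter(params_by_country, parameter_path, high, country),
            horizon,
        ).sum()
    )
    return low_val, high_val, abs(high_val - low_val)


def tornado(
    portfolio: Iterable[Product],
    params_by_country: Mapping[str, PolicyParameterSet],
    items: Sequence[tuple[str, float, float]],
    country: str = "all",
    horizon: ForecastHorizon = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """One-way analysis over several ``(path, low, high)`` items.

    Returns a frame sorted by descending swing — the usual tornado order.
    """
    products = list(portfolio)
    rows = []
    for path, low, high in items:
        low_val, high_val, swing = one_way(
            products, params_by_country, path, low, high, country, horizon
        )
        rows.append(
            {"parameter": path, "low": low_val, "high": high_val, "swing": swing}
        )
    frame = pd.DataFrame(rows).sort_values("swing", ascending=False, kind="stable")
    return frame.reset_index(drop=True)


def probabilistic(
    portfolio: Iterable[Product],
    params_by_country: Mapping[str, PolicyParameterSet],
    specs: Sequence[ParameterDistributionSpec],
    n_draws: int,
    seed: int,
    horizon: ForecastHorizon = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """Monte-Carlo propagation of parameter uncertainty.

    Per draw, every spec is sampled independently and applied, then the
    forecast is re-run; the per-country cumulative payer net impact is
    summarized as mean, p2.5, p50 and p97.5. Deterministic given ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not specs:
        raise ValueError("no distribution specs given")
    products = list(portfolio)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        params = params_by_country
        for spec in specs:
            params = set_parameter(params, spec.path, spec.sample(rng), spec.country)
        draws.append(_net_cumulative(products, params, horizon))
    sample = pd.DataFrame(draws)
    summary = pd.DataFrame(
        {
            "mean": sample.mean(),
            "p2.5": sample.quantile(0.025),
            "p50": sample.quantile(0.50),
            "p97.5": sample.quantile(0.975),
        }
    )
    summary.index.name = "country"
    return summary


_DEFAULT_PATHS = (
    "generic_retail.price_reduction",
    "generic_retail.max_penetration",
    "biosimilar_retail.price_reduction",
    "biosimilar_retail.max_penetration",
)


def default_specs(
    params_by_country: Mapping[str, PolicyParameterSet], rel: float = 0.2
) -> list[ParameterDistributionSpec]:
    """±``rel`` relative uniform ranges on the retail market fractions."""
    specs = []
    for country, params in params_by_country.items():
        for path in _DEFAULT_PATHS:
            segment, fname = path.split(".")
            value = getattr(getattr(params, segment), fname)
            specs.append(
                ParameterDistributionSpec(
                    path=path,
                    country=country,
                    kind="uniform",
                    low=max(0.0, value * (1.0 - rel)),
                    high=min(1.0, value * (1.0 + rel)),
                )
            )
    return specs
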