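"""Result rendering in the study's table layouts.

Three styles:

* ``yearly_and_cumulative`` — one row per country, yearly net impacts plus
  the horizon cumulative; savings print negative.
* ``net_impact_vs_base`` — base vs scenario cumulative net and the delta;
  savings print negative.
* ``biosimilar_savings`` — base vs hospital-shift biosimilar savings and the
  extra savings; savings print positive.

Values are printed in € millions, rounded half away from zero, with ASCII
minus signs; rendering is a pure function of the result object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .engine import BudgetImpactResult

__all__ = ["ReportSpec", "round_half_away", "render", "write_result_csv"]

_STYLES = ("yearly_and_cumulative", "net_impact_vs_base", "biosimilar_savings")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (543.63 → 544)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class ReportSpec:
    """Rendering choices: layout and the unit of the incoming values."""

    table_style: str
    input_units: str = "eur"  # or "eur_million"

    def __post_init__(self):
        if self.table_style not in _STYLES:
            raise ValueError(f"table_style must be one of {_STYLES}")
        if self.input_units not in ("eur", "eur_million"):
            raise ValueError("input_units must be 'eur' or 'eur_million'")

    def to_millions(self, value: float) -> float:
        return value / 1e6 if self.input_units == "eur" else value


def _fmt(value: float) -> str:
    return f"{round_half_away(value):,d}".replace("−", "-")


def render(result_or_comparison, spec: ReportSpec) -> tuple[pd.DataFrame, str]:
    """Render a result or comparison as a rounded € million table plus text.

    ``yearly_and_cumulative`` takes a :class:`BudgetImpactResult`; the two
    comparison styles take the frame produced by ``scenarios.compare``
    (columns base / scenario / delta).
    """
    if spec.table_style == "yearly_and_cumulative":
        result: BudgetImpactResult = result_or_comparison
        yearly = result.yearly()["net"].unstack("year")
        span = f"{min(result.years)}-{max(result.years)}"
        yearly[span] = result.net_cumulative()
        table = yearly.map(spec.to_millions)
    else:
        frame = result_or_comparison
        missing = {"base", "scenario", "delta"} - set(frame.columns)
        if missing:
            raise ValueError(f"comparison frame missing columns {sorted(missing)}")
        table = frame[["base", "scenario", "delta"]].map(spec.to_millions)
        if spec.table_style == "biosimilar_savings":
            table = table.rename(columns={"delta": "extra_savings"})
    rounded = table.map(round_half_away)
    lines = [rounded.to_string(formatters={c: _fmt for c in rounded.columns})]
    text = "\n".join(lines).replace("−", "-") + "\n"
    return rounded, text


def write_result_csv(result: BudgetImpactResult, path: str | Path) -> None:
    """Write a tidy result CSV: country, year, component, perspective, M€."""
    tidy = result.tidy()
    tidy["value_eur_millions"] = tidy.pop("value_eur") / 1e6
    tidy.to_csv(path, index=False)
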