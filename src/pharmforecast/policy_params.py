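"""Per-country market-access and reimbursement parameters.

Each country is described by the policy levers that drive off-patent market
dynamics and the entry of new branded products:

* how long after marketing authorization a new brand reaches the market,
* for each distribution segment (generic retail, biosimilar retail, hospital):
  the copy's time to market after loss of exclusivity, its price discount vs
  the originator, the steady-state volume share it captures, the time taken
  to reach that share, and the price cut the originator applies at copy entry,
* the public payer's reimbursement rate.

All rates are stored as fractions in [0, 1]; config files at the I/O boundary
use percentages (``*_pct`` keys) so they can be transcribed directly from
published policy tables.
"""

from __future__ import annotations

import io
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "COUNTRIES",
    "SegmentParams",
    "PolicyParameterSet",
    "canonical_country",
    "base_case_parameters",
    "load_parameter_sets",
    "save_parameter_sets",
    "default_parameter_file",
]

#: The seven EU member states covered by the base-case parameter table.
COUNTRIES = (
    "France",
    "Germany",
    "Greece",
    "Hungary",
    "Poland",
    "Portugal",
    "United Kingdom",
)

_ALIASES = {
    "uk": "United Kingdom",
    "gb": "United Kingdom",
    "great britain": "United Kingdom",
}


def canonical_country(name: str) -> str:
    """Resolve a country name case-insensitively to its canonical form.

    Raises ``KeyError`` for names outside the built-in country set.
    """
    key = name.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    for country in COUNTRIES:
        if key == country.lower():
            return country
    raise KeyError(f"unknown country: {name!r}")


class SegmentParams(BaseModel):
    """Copy-entry dynamics for one distribution segment.

    Parameters
    ----------
    time_to_market_days:
        Delay from loss of exclusivity to effective copy entry, in days
        (pricing & reimbursement procedures).
    price_reduction:
        Copy price discount vs the originator, fraction of the originator
        price.
    max_penetration:
        Steady-state volume share of the off-patent market captured by
        copies.
    ramp_months:
        Months from copy entry to reach ``max_penetration`` (linear ramp).
    brand_price_impact:
        Price cut the originator applies to its own product at copy entry.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    time_to_market_days: int = Field(ge=0)
    price_reduction: float = Field(ge=0.0, le=1.0)
    max_penetration: float = Field(ge=0.0, le=1.0)
    ramp_months: int = Field(ge=0)
    brand_price_impact: float = Field(ge=0.0, le=1.0)


class PolicyParameterSet(BaseModel):
    """One country's full policy parameter set.

    ``reimbursement_rate`` must be strictly positive: the coverage-expansion
    scenario divides the payer-perspective impact by it.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    country: str
    brand_ttm_months: int = Field(ge=0)
    generic_retail: SegmentParams
    biosimilar_retail: SegmentParams
    hospital: SegmentParams
    reimbursement_rate: float = Field(gt=0.0, le=1.0)


def _seg(ttm_days: int, reduction: float, penetration: float,
         ramp: int, brand_impact: float) -> SegmentParams:
    return SegmentParams(
        time_to_market_days=ttm_days,
        price_reduction=reduction,
        max_penetration=penetration,
        ramp_months=ramp,
        brand_price_impact=brand_impact,
    )


# Hospital procurement (tenders) is modelled identically everywhere: immediate
# entry, deep 80% discount, full substitution, no originator price response.
_HOSPITAL = (0, 0.80, 1.00, 0, 0.0)

# Base-case policy parameters for the seven countries:
# (brand ttm months,
#  generic retail  (ttm days, price cut, penetration, ramp months, brand impact),
#  biosimilar retail (...same fields...),
#  reimbursement rate)
_BASE_CASE: dict[str, tuple[int, tuple, tuple, float]] = {
    "France": (12, (60, 0.60, 0.80, 36, 0.20), (470, 0.30, 0.15, 36, 0.10), 0.69),
    "Germany": (0, (0, 0.55, 0.85, 12, 0.0), (180, 0.25, 0.25, 12, 0.0), 0.90),
    "Greece": (12, (270, 0.60, 0.25, 36, 0.50), (450, 0.25, 0.05, 36, 0.25), 0.80),
    "Hungary": (12, (45, 0.55, 1.00, 18, 0.0), (580, 0.50, 1.00, 18, 0.0), 0.67),
    "Poland": (12, (180, 0.45, 0.85, 24, 0.25), (540, 0.45, 0.25, 24, 0.12), 0.625),
    "Portugal": (12, (150, 0.60, 0.25, 30, 0.0), (530, 0.30, 0.15, 30, 0.0), 0.816),
    "United Kingdom": (12, (0, 0.75, 0.80, 12, 0.0), (180, 0.25, 0.15, 12, 0.0), 1.00),
}


def base_case_parameters() -> dict[str, PolicyParameterSet]:
    """Return the built-in base-case parameter sets for all seven countries."""
    out: dict[str, PolicyParameterSet] = {}
    for country, (brand_ttm, gen, bio, rate) in _BASE_CASE.items():
        out[country] = PolicyParameterSet(
            country=country,
            brand_ttm_months=brand_ttm,
            generic_retail=_seg(*gen),
            biosimilar_retail=_seg(*bio),
            hospital=_seg(*_HOSPITAL),
            reimbursement_rate=rate,
        )
    return out


# --------------------------------------------------------------------------
# Config-file serialization. Percent-denominated keys mirror how policy
# tables are published; internal representation is always fractional.

_SEG_FIELDS = {
    "time_to_market_days": ("time_to_market_days", 1.0),
    "price_reduction_pct": ("price_reduction", 0.01),
    "max_penetration_pct": ("max_penetration", 0.01),
    "ramp_months": ("ramp_months", 1.0),
    "brand_price_impact_pct": ("brand_price_impact", 0.01),
}

_SEGMENTS = ("generic_retail", "biosimilar_retail", "hospital")


def _segment_from_config(raw: Mapping[str, Any], where: str) -> dict[str, Any]:
    if not isinstance(raw, Mapping):
        raise ValueError(f"{where}: expected a mapping of segment fields")
    unknown = set(raw) - set(_SEG_FIELDS)
    if unknown:
        raise ValueError(f"{where}: unknown fields {sorted(unknown)}")
    missing = set(_SEG_FIELDS) - set(raw)
    if missing:
        raise ValueError(f"{where}: missing fields {sorted(missing)}")
    out = {}
    for key, value in raw.items():
        field, scale = _SEG_FIELDS[key]
        # divide rather than multiply by 0.01: correctly-rounded, so the
        # percent form round-trips to the exact internal fraction
        out[field] = value / 100.0 if scale != 1.0 else value
    return out


def _segment_to_config(seg: SegmentParams) -> dict[str, Any]:
    return {
        "time_to_market_days": seg.time_to_market_days,
        "price_reduction_pct": round(seg.price_reduction * 100, 6),
        "max_penetration_pct": round(seg.max_penetration * 100, 6),
        "ramp_months": seg.ramp_months,
        "brand_price_impact_pct": round(seg.brand_price_impact * 100, 6),
    }


def _set_from_config(country: str, raw: Mapping[str, Any]) -> PolicyParameterSet:
    if not isinstance(raw, Mapping):
        raise ValueError(f"{country}: expected a mapping of parameter fields")
    expected = {"brand_time_to_market_months", "reimbursement_rate_pct", *_SEGMENTS}
    unknown = set(raw) - expected
    if unknown:
        raise ValueError(f"{country}: unknown fields {sorted(unknown)}")
    missing = expected - set(raw)
    if missing:
        raise ValueError(f"{country}: missing fields {sorted(missing)}")
    data: dict[str, Any] = {
        "country": country,
        "brand_ttm_months": raw["brand_time_to_market_months"],
        "reimbursement_rate": raw["reimbursement_rate_pct"] / 100.0,
    }
    for seg_name in _SEGMENTS:
        data[seg_name] = _segment_from_config(raw[seg_name], f"{country}.{seg_name}")
    return PolicyParameterSet.model_validate(data)


def load_parameter_sets(
    config_source: str | Path | io.TextIOBase | Mapping[str, Any],
    *,
    allow_custom_countries: bool = False,
) -> dict[str, PolicyParameterSet]:
    """Load validated parameter sets from a YAML/JSON document.

    The document is keyed by country; country names are matched
    case-insensitively against the canonical built-in names unless
    ``allow_custom_countries`` is set. Unknown fields, missing fields and
    out-of-range values are rejected.
    """
    if isinstance(config_source, Mapping):
        doc = config_source
    elif isinstance(config_source, (str, Path)):
        text = Path(config_source).read_text()
        doc = yaml.safe_load(text)
    else:
        doc = yaml.safe_load(config_source.read())
    if not isinstance(doc, Mapping):
        raise ValueError("parameter config must be a mapping keyed by country")
    out: dict[str, PolicyParameterSet] = {}
    for raw_name, raw_params in doc.items():
        try:
            country = canonical_country(str(raw_name))
        except KeyError:
            if not allow_custom_countries:
                raise
            country = str(raw_name)
        out[country] = _set_from_config(country, raw_params)
    return out


def save_parameter_sets(
    params_by_country: Mapping[str, PolicyParameterSet],
    path: str | Path | None = None,
    *,
    fmt: str = "yaml",
) -> str:
    """Serialize parameter sets to the percent-denominated config format.

    Returns the document text; writes it to ``path`` when given.
    """
    doc: dict[str, Any] = {}
    for country in params_by_country:
        ps = params_by_country[country]
        doc[country] = {
            "brand_time_to_market_months": ps.brand_ttm_months,
            "reimbursement_rate_pct": round(ps.reimbursement_rate * 100, 6),
            **{seg: _segment_to_config(getattr(ps, seg)) for seg in _SEGMENTS},
        }
    if fmt == "json":
        text = json.dumps(doc, indent=2)
    else:
        text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def default_parameter_file() -> Path:
    """Path to the bundled base-case parameter config."""
    return Path(resources.files("pharmforecast").joinpath("data/base_case_params.yaml"))
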