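# Methods

## Model structure

The forecaster is a deterministic monthly simulation over January 2012 –
December 2016 (60 steps). Each product is independent; the portfolio result
is the sum of product-level series, so the engine is linear in every sales
base and affine in every price fraction. No discounting is applied and all
values are constant 2011 euros: the quantity of interest is the budget
*delta* against the 2011 baseline, not a net present value.

### Off-patent dynamics

A product that loses exclusivity in month `t_LoE` is split by value into a
retail and a hospital chain (`retail_share`). In each chain, copies enter at
`t_LoE + time_to_market` and capture a volume share

    p(m) = 0                                   m < entry
    p(m) = p_max · min(1, (m − entry)/ramp)    ramp > 0
    p(m) = p_max                               ramp = 0, m ≥ entry

The monthly saving versus the no-expiry counterfactual, with total volume
held constant, is

    S_chain/12 · [ p(m)·d + (1 − p(m))·b·1(m ≥ entry) ]

where `d` is the copy discount and `b` the originator's own step price cut
at copy entry. The originator cut is a one-off step, not a decay path — no
erosion dynamics beyond the step are modelled. Small molecules follow the
generic-retail segment, biologics the biosimilar-retail segment; the
hospital segment (immediate tender entry, 80% discount, 100% substitution,
no originator response) is common to both and identical across countries.

Penetration is a *volume* share applied to a *value* base: with constant
total volume the expenditure saving per euro of pre-expiry sales is exactly
`p·d + (1−p)·b`, which also makes savings exactly linear in `d` when
`b = 0` — the property the hospital-shift scenario exploits.

### Innovative entries

A pipeline product approved in month `t_a` launches at
`t_a + brand_ttm_months`. Its k-th month on the market books
`min(1, k/uptake_months)` of the peak monthly value `peak/12`, i.e. a
linear uptake that reaches peak after `uptake_months` and stays flat; sales
beyond the horizon are simply not counted. New-product sales are treated as
purely additional cost — no cannibalization of the existing market.

### Time conventions

The grid is monthly; day-denominated times to market convert as
`round(days / 30.44)` (nearest whole month, 30.44 = mean Gregorian month).
Monthly resolution is the coarsest grid that still separates the segment
delays in the base-case table, which range from 45 to 580 days. Expiry dates
may precede 2012, in which case the ramp is already in progress when the
horizon opens.

### Perspectives

Series are computed at the society level. The payer view multiplies every
component by the country's reimbursement rate, uniformly across chains and
components — patients/private insurers bear the complement. The
manufacturer view flips the sign of the savings components (copy
substitution is industry revenue loss) and keeps innovation as revenue
gain. `net = innovation − generic − biosimilar` holds in every view;
savings components are stored positive and a negative net is an overall
saving.

## Scenarios

Scenarios are declarative patches over the parameter sets, applied to deep
copies and re-validated, so application is idempotent and cannot silently
push a parameter out of range. Two mechanisms are not expressible as
patches:

* **Coverage expansion (s5).** With reimbursement raised to 100%, every
  market movement previously reimbursed at rate `r` is borne in full, so
  the cumulative payer impact rescales to `base/r`; on top of that the
  payer absorbs, once, the share of the 2011 expenditure base previously
  paid by patients, `(1 − r) ×` total 2011 sales. The one-off cost is added
  to the cumulative figure only, not once per year — this is the
  arithmetic that reproduces the published scenario figures cell by cell.
* **Biosimilar hospital shift (s9).** All off-patent biologic value is
  routed through the hospital chain under tender conditions (immediate
  entry, full substitution, no ramp, no originator response) at a chosen
  discount (50% or 80%). Reported as the biosimilar-savings component in
  isolation, positive sign, payer perspective — the convention of the
  published channel-shift table. Because `b = 0` and `p = 1` on this
  pathway, savings are exactly proportional to the discount.

The UK-transplant scenario (s1) copies the UK's brand time to market and
generic/biosimilar retail segments but *not* its 100% reimbursement rate:
the scenario probes market-access dynamics, and copying the rate would
conflate them with the coverage-expansion effect that s5 isolates. Hospital
parameters are identical across countries, so whether they are "copied" is
moot.

## Synthetic portfolios

Real product-level national sales extracts are proprietary, so portfolios
are generated: per country, `n_offpatent` expiry candidates and
`n_pipeline` entrants, with log-normal sales magnitudes (median €40 m/yr,
σ = 1 — value concentrated in a blockbuster tail), Beta(4, 2) retail value
shares (mean two-thirds retail), a 25% biologic share, expiries uniform
over 2010–2016 and approvals uniform over 2012 – mid-2016. These
composition statistics are not published anywhere; the defaults are one
fixed, documented choice of a plausible market and are not tuned per
country. Generation uses a single seeded stream in country → product →
field order, so portfolios are bit-reproducible and a country's draw does
not depend on which other countries are requested after it.

What the generator does **not** emulate: real expiry calendars (the actual
clustering of big expiries in 2012–2013), country-specific market
composition, molecule identities, market volume growth, price-level
differences between countries, or correlation between size and channel
split. Tests passing on synthetic portfolios therefore validate the
*mechanics* (accounting identities, linearity, monotonicity, scenario
algebra), not the country-level euro magnitudes, which require the real
extract.

`calibrate_total` rescales a country's sales uniformly to a target 2011
total; since the engine is homogeneous of degree one in the sales base,
every euro output scales by the same factor. This is how the published
80%-discount hospital-shift figures are matched before re-running at 50%:
the re-run is then determined by linearity alone, independent of the
portfolio's composition or seed (verification uses 20-product all-biologic
portfolios per country).

## Sensitivity analysis

One-way analysis re-runs the forecast at the two bounds of one parameter
(all else fixed) and reports the swing of the cumulative payer net impact;
the tornado helper ranks several parameters. The probabilistic analysis
draws each specified parameter independently per iteration — uniform,
scaled Beta or triangular — re-runs the forecast, and summarizes the
per-country cumulative net impact as mean and 2.5/50/97.5 percentiles. The
original elicited distributions are not published; the shipped default is
an illustrative ±20% relative uniform band (truncated to [0, 1]) on the
retail discount and penetration fractions. No correlation structure is
imposed. Internal checks run 2,000 draws on a six-product portfolio, where
the Monte-Carlo mean of an affine response must match the midpoint run.

## Numerical choices

* Fractions are stored in [0, 1] internally; config files use percentages
  (`*_pct`), converted by division (correctly rounded, so the bundled
  percent table round-trips to exact fractions).
* Reported tables are € millions rounded half away from zero, matching the
  published rounding (543.63 → 544); net-impact tables print savings
  negative, the biosimilar channel-shift table prints savings positive.
* A zero penetration ramp is a step to the ceiling at the entry month; a
  positive ramp starts at zero share in the entry month.
* Engine/oracle agreement is asserted to 1e-9 relative tolerance on
  ~50-product portfolios against a plain month-by-month loop.
* Country names are matched case-insensitively against canonical English
  names; unknown countries are rejected unless explicitly allowed.

## Limitations

No exchange rates, inflation, rebates/clawbacks, tender mechanics beyond
the hospital discount, volume growth, or cross-product substitution. The
sales base is an abstract value level (the price basis — ex-factory vs
reimbursed — is whatever the input extract uses). Uptake and penetration
shapes are linear for lack of published shape information; the published
cross-table identities the package verifies are shape-invariant, so this
choice is untestable against the published figures and is flagged as a
modelling assumption.
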