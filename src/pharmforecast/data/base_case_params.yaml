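# Base-case policy parameters for the seven-country EU forecast.
# Percent-denominated fields carry a _pct suffix; durations are in the unit
# named in the key. The hospital segment is identical across countries:
# immediate tender-driven entry, 80% discount, full substitution.
France:
  brand_time_to_market_months: 12
  reimbursement_rate_pct: 69
  generic_retail:
    time_to_market_days: 60
    price_reduction_pct: 60
    max_penetration_pct: 80
    ramp_months: 36
    brand_price_impact_pct: 20
  biosimilar_retail:
    time_to_market_days: 470
    price_reduction_pct: 30
    max_penetration_pct: 15
    ramp_months: 36
    brand_price_impact_pct: 10
  hospital:
    time_to_market_days: 0
    price_reduction_pct: 80
    max_penetration_pct: 100
    ramp_months: 0
    brand_price_impact_pct: 0
Germany:
  brand_time_to_market_months: 0
  reimbursement_rate_pct: 90
  generic_retail:
    time_to_market_days: 0
    price_reduction_pct: 55
    max_penetration_pct: 85
    ramp_months: 12
    brand_price_impact_pct: 0
  biosimilar_retail:
    time_to_market_days: 180
    price_reduction_pct: 25
    max_penetration_pct: 25
    ramp_months: 12
    brand_price_impact_pct: 0
  hospital:
    time_to_market_days: 0
    price_reduction_pct: 80
    max_penetration_pct: 100
    ramp_months: 0
    brand_price_impact_pct: 0
Greece:
  brand_time_to_market_months: 12
  reimbursement_rate_pct: 80
  generic_retail:
    time_to_market_days: 270
    price_reduction_pct: 60
    max_penetration_pct: 25
    ramp_months: 36
    brand_price_impact_pct: 50
  biosimilar_retail:
    time_to_market_days: 450
    price_reduction_pct: 25
    max_penetration_pct: 5
    ramp_months: 36
    brand_price_impact_pct: 25
  hospital:
    time_to_market_days: 0
    price_reduction_pct: 80
    max_penetration_pct: 100
    ramp_months: 0
    brand_price_impact_pct: 0
Hungary:
  brand_time_to_market_months: 12
  reimbursement_rate_pct: 67
  generic_retail:
    time_to_market_days: 45
    price_reduction_pct: 55
    max_penetration_pct: 100
    ramp_months: 18
    brand_price_impact_pct: 0
  biosimilar_retail:
    time_to_market_days: 580
    price_reduction_pct: 50
    max_penetration_pct: 100
    ramp_months: 18
    brand_price_impact_pct: 0
  hospital:
    time_to_market_days: 0
    price_reduction_pct: 80
    max_penetration_pct: 100
    ramp_months: 0
    brand_price_impact_pct: 0
Poland:
  brand_time_to_market_months: 12
  reimbursement_rate_pct: 62.5
  generic_retail:
    time_to_market_days: 180
    price_reduction_pct: 45
    max_penetration_pct: 85
    ramp_months: 24
    brand_price_impact_pct: 25
  biosimilar_retail:
    time_to_market_days: 540
    price_reduction_pct: 45
    max_penetration_pct: 25
    ramp_months: 24
    brand_price_impact_pct: 12
  hospital:
    time_to_market_days: 0
    price_reduction_pct: 80
    max_penetration_pct: 100
    ramp_months: 0
    brand_price_impact_pct: 0
Portugal:
  brand_time_to_market_months: 12
  reimbursement_rate_pct: 81.6
  generic_retail:
    time_to_market_days: 150
    price_reduction_pct: 60
    max_penetration_pct: 25
    ramp_months: 30
    brand_price_impact_pct: 0
  biosimilar_retail:
    time_to_market_days: 530
    price_reduction_pct: 30
    max_penetration_pct: 15
    ramp_months: 30
    brand_price_impact_pct: 0
  hospital:
    time_to_market_days: 0
    price_reduction_pct: 80
    max_penetration_pct: 100
    ramp_months: 0
    brand_price_impact_pct: 0
United Kingdom:
  brand_time_to_market_months: 12
  reimbursement_rate_pct: 100
  generic_retail:
    time_to_market_days: 0
    price_reduction_pct: 75
    max_penetration_pct: 80
    ramp_months: 12
    brand_price_impact_pct: 0
  biosimilar_retail:
    time_to_market_days: 180
    price_reduction_pct: 25
    max_penetration_pct: 15
    ramp_months: 12
    brand_price_impact_pct: 0
  hospital:
    time_to_market_days: 0
    price_reduction_pct: 80
    max_penetration_pct: 100
    ramp_months: 0
    brand_price_impact_pct: 0
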