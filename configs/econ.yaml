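# Cost ranges (euros, 2015 price level) per screen and discounting.
cost_ranges:
  screening: [15.25, 41.07]
  travel: [1.58, 14.19]
  productivity: [2.63, 16.62]
discount_rate_costs: 0.04
discount_rate_effects: 0.015
perspective: healthcare
price_year: 2015
gamma_fit: quantile      # match (min, max) to the 2.5%/97.5% quantiles
discount_effects: false  # delayed-diagnosis counts reported undiscounted
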