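schema: 1
settings:
  cohort_size: 100000
  cycles: 40
  discount_rate: 0.05
  discount_low: 0.0
  discount_high: 0.08
  half_cycle_correction: false
wtp:
  gdp_per_capita: 78951.15
shared:
  mortality_gold12: 0.0286
  mortality_gold34: 0.126
  severe_ae_fatality: 0.032
  apply_ae_fatality: true
  mild_ae_utility_multiplier: 0.85
  severe_ae_utility_multiplier: 0.3
  ae_duration_years: 0.041666666666666664
  ae_incidence: 1.0
arms:
  western:
    enrolled_gold12: 45
    enrolled_gold34: 34
    costs:
      gold12:
        stable: {mean: 2998.36, sd: 1750.01}
        mild_ae: {mean: 7345.33, sd: 10753.48}
        severe_ae: {mean: 17882.67, sd: 15426.19}
      gold34:
        stable: {mean: 5324.59, sd: 985.55}
        mild_ae: {mean: 9795.0, sd: 17208.92}
        severe_ae: {mean: 10735.0, sd: 7861.86}
    utilities:
      gold12:
        baseline: {mean: 0.66, sd: 0.099}
        month6: {mean: 0.691, sd: 0.123}
      gold34:
        baseline: {mean: 0.657, sd: 0.099}
        month6: {mean: 0.678, sd: 0.105}
    probabilities:
      mild_ae_gold12: 0.67
      severe_ae_gold12: 0.33
      mild_ae_gold34: 0.5
      severe_ae_gold34: 0.5
      progression: 0.215
  tcm:
    enrolled_gold12: 43
    enrolled_gold34: 36
    costs:
      gold12:
        stable: {mean: 6829.0, sd: 525.18}
        mild_ae: {mean: 5974.76, sd: 11563.94}
        severe_ae: {mean: 12660.0, sd: 16772.57}
      gold34:
        stable: {mean: 7015.94, sd: 462.63}
        mild_ae: {mean: 2567.78, sd: 1170.4}
        severe_ae: {mean: 8267.75, sd: 7123.0}
    utilities:
      gold12:
        baseline: {mean: 0.679, sd: 0.108}
        month6: {mean: 0.692, sd: 0.107}
      gold34:
        baseline: {mean: 0.641, sd: 0.103}
        month6: {mean: 0.702, sd: 0.084}
    probabilities:
      mild_ae_gold12: 0.82
      severe_ae_gold12: 0.18
      mild_ae_gold34: 0.53
      severe_ae_gold34: 0.47
      progression: 0.17
  combined:
    enrolled_gold12: 39
    enrolled_gold34: 39
    costs:
      gold12:
        stable: {mean: 9342.12, sd: 1621.49}
        mild_ae: {mean: 1597.5, sd: 1610.06}
        severe_ae: {mean: 8200.0, sd: 282.84}
      gold34:
        stable: {mean: 11306.64, sd: 770.09}
        mild_ae: {mean: 2557.78, sd: 1780.6}
        severe_ae: {mean: 6605.72, sd: 5450.84}
    utilities:
      gold12:
        baseline: {mean: 0.697, sd: 0.074}
        month6: {mean: 0.709, sd: 0.102}
      gold34:
        baseline: {mean: 0.705, sd: 0.094}
        month6: {mean: 0.713, sd: 0.121}
    probabilities:
      mild_ae_gold12: 0.67
      severe_ae_gold12: 0.33
      mild_ae_gold34: 0.53
      severe_ae_gold34: 0.47
      progression: 0.124
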