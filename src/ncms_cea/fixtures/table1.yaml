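# Base-case inputs of the NCMS cost-effectiveness model (2013 Int$).
# Each uncertain scalar carries base/low/high; the low/high bounds feed the
# one-way sensitivity analyses and the triangular PSA distributions.
# The referenced schedules are SYNTHETIC stand-ins (Gompertz-Makeham
# mortality, logistic hypertension incidence) for the unpublished national
# life table and hypertension schedule; see ncms_cea.synthetic.
effects:
  mortality_per_1000:        # marginal effect on annual deaths per 1,000
    male:
      "20-44": {base: -0.10, low: -0.28, high: 0.08}
      "45-59": {base: -0.14, low: -0.57, high: 0.29}
      "60+": {base: 0.36, low: -3.01, high: 3.73}
    female:
      "20-44": {base: -0.05, low: -0.12, high: 0.03}
      "45-59": {base: -0.05, low: -0.32, high: 0.23}
      "60+": {base: 1.05, low: -1.72, high: 3.82}
  rr_hypertension: {base: 0.98, low: 0.95, high: 1.00}
utilities:
  normotensive: {base: 0.98, low: 0.98, high: 0.98}
  hypertensive: {base: 0.92, low: 0.90, high: 0.94}
costs:
  total_health_expenditure: {base: 359, low: 243, high: 977}  # Int$/resident-year
  growth_rate: {base: 0.61, low: 0.50, high: 0.70}
  htn_annual_cost: {base: 392, low: 344, high: 441}           # Int$/patient-year
  ppp_rate: 3.55                                              # CNY per Int$, reporting only
labor:
  baseline_offfarm_p: 0.17
  d_offfarm_p:                 # increase in off-farm participation probability
    "30-49": {base: 0.13, low: 0.07, high: 0.20}
    "50+": {base: 0.07, low: 0.03, high: 0.11}
  d_farm_hours:                # increase in agricultural hours per year
    "30-49": {base: 1.10, low: 0.84, high: 1.44}
    "50+": {base: 1.28, low: 1.07, high: 1.53}
  annual_wage: {base: 1029, low: 350, high: 4198}             # Int$/year
  agri_hourly: {base: 1.44, low: 0.47, high: 2.59}            # Int$/hour
econ:
  discount_rate: {base: 0.03, low: 0.00, high: 0.05}
  gdp_per_capita: 12353
  wtp_multiplier: 3
  start_age: 20
  end_age: 100
  sex_weights: {male: 0.5, female: 0.5}
schedules:
  mortality: mortality_synthetic.csv
  incidence: htn_incidence_synthetic.csv
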