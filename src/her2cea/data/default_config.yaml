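# Default model configuration: base-case parameter values with their
# probabilistic-sensitivity-analysis distributions, model settings, the
# parametric background-mortality life table, and the five shipped
# neoadjuvant-adjuvant treatment strategies.
#
# Distribution families and the meaning of shape1/shape2:
#   beta        shape1 = alpha, shape2 = beta; support (0, 1)
#   gamma       shape1 = alpha (shape), shape2 = beta (SCALE, mean = alpha*beta)
#   lognormal   shape1 = mu, shape2 = sigma (log scale)
#   truncnormal shape1 = lower bound a, shape2 = upper bound b,
#               loc/scale given separately (loc defaults to the base value,
#               scale to 20% of loc)
#   normal      shape1 = mean, shape2 = sd
#   point       degenerate at the base value (shape fields unused)
#
# All costs are 2020 USD. Probabilities are unitless; median survivals are
# months; ages/durations are years.

settings:
  start_age: 49
  cycle_length: 1.0
  horizon_age: 100
  discount_rate: 0.03
  wtp_thresholds: [50000, 100000, 150000]
  wtp_grid: {start: 0, stop: 200000, step: 1000}
  psa_iterations: 1000
  rng_seed: 2027074
  toxicity_mode: lifetime   # or first_cycle

life_table:
  kind: gompertz_makeham
  makeham: 5.0e-4      # age-independent hazard, per year
  scale: 3.5e-5        # Gompertz scale b, per year
  shape: 0.094         # Gompertz shape theta, per year of age

parameters:
  pcr_prob:
    HP:       {value: 0.168, dist: {family: beta, shape1: 18.0,  shape2: 89.0}}
    THP:      {value: 0.458, dist: {family: beta, shape1: 49.0,  shape2: 58.0}}
    DDAC_THP: {value: 0.565, dist: {family: beta, shape1: 78.0,  shape2: 60.0}}
    TCHP:     {value: 0.525, dist: {family: beta, shape1: 115.0, shape2: 104.0}}
  dr3y_ref:   {value: 0.159, dist: {family: beta, shape1: 118.0, shape2: 625.0}}
  rr_dr:
    TDM1:          {value: 0.60, dist: {family: lognormal, shape1: -0.51, shape2: 0.09}}
    DDACTHP_TDM1:  {value: 0.52, dist: {family: truncnormal, shape1: 0.18, shape2: 0.60}}
    DDAC_TDM1:     {value: 0.40, dist: {family: truncnormal, shape1: 0.18, shape2: 0.60}}
    H_PCR:         {value: 0.18, dist: {family: lognormal, shape1: -1.70, shape2: 0.18}}
    H:             {value: 1.0,  dist: {family: point}}   # reference group
  lr3y_ref:   {value: 0.046, dist: {family: beta, shape1: 34.0, shape2: 709.0}}
  rr_lr:      {value: 0.24,  dist: {family: lognormal, shape1: -1.43, shape2: 0.11}}
  p_dr_after_lr_10y: {value: 0.189, dist: {family: beta, shape1: 13.0, shape2: 56.0}}
  median_surv_dr_months:  {value: 38.0, dist: {family: normal, shape1: 38.0, shape2: 4.08}}
  median_surv_aml_months: {value: 8.0,  dist: {family: normal, shape1: 8.0,  shape2: 2.0}}
  p_chf_death_annual: {value: 0.127, dist: {family: beta, shape1: 69.93, shape2: 488.07}}
  chf1y_ref:  {value: 0.037, dist: {family: beta, shape1: 100.32, shape2: 2647.72}}
  rr_chf_ac:  {value: 1.26,  dist: {family: lognormal, shape1: 0.23, shape2: 0.08}}
  # Base case uses the 0.1% point estimate; the PSA samples the published beta,
  # whose own mean (~0.0007) sits below the printed point value.
  aml1y_ref:  {value: 0.001, dist: {family: beta, shape1: 138.30, shape2: 197505.60}}
  rr_aml_nonac: {value: 0.88, dist: {family: lognormal, shape1: -0.13, shape2: 0.35}}
  rr_aml_ac:    {value: 1.68, dist: {family: lognormal, shape1: 0.52,  shape2: 0.28}}
  cost_neoadjuvant:
    HP:       {value: 64389.0,  dist: {family: gamma, shape1: 25.0, shape2: 2575.56}}
    THP:      {value: 65428.0,  dist: {family: gamma, shape1: 25.0, shape2: 2617.10}}
    DDAC_THP: {value: 106787.0, dist: {family: gamma, shape1: 25.0, shape2: 4271.49}}
    TCHP:     {value: 153257.0, dist: {family: gamma, shape1: 25.0, shape2: 6130.28}}
  cost_adjuvant:
    H:              {value: 108995.0, dist: {family: gamma, shape1: 25.0, shape2: 4359.78}}
    TDM1:           {value: 157871.0, dist: {family: gamma, shape1: 25.0, shape2: 6314.82}}
    DDACTHP_TDM1:   {value: 264658.0, dist: {family: gamma, shape1: 25.0, shape2: 10586.32}}
    DDAC_TDM1:      {value: 199230.0, dist: {family: gamma, shape1: 25.0, shape2: 7969.21}}
    H_POST_TCHP:    {value: 93424.0,  dist: {family: gamma, shape1: 25.0, shape2: 3736.96}}
    TDM1_POST_TCHP: {value: 135318.0, dist: {family: gamma, shape1: 25.0, shape2: 5412.70}}
  cost_lr_first_year: {value: 21005.0, dist: {family: gamma, shape1: 25.0, shape2: 840.20}}
  cost_lr_subsequent: {value: 2335.0,  dist: {family: gamma, shape1: 25.0, shape2: 93.41}}
  cost_dr_annual:     {value: 144865.0, dist: {family: gamma, shape1: 25.0, shape2: 5794.62}}
  cost_chf_initial:   {value: 36748.0, dist: {family: gamma, shape1: 25.0, shape2: 1469.92}}
  cost_chf_annual:    {value: 7035.0,  dist: {family: gamma, shape1: 25.0, shape2: 281.40}}
  # beta printed as a rate for this row: scale 8.44 gives mean 2530.10*8.44 = 21354
  cost_aml_lifetime:  {value: 21345.0, dist: {family: gamma, shape1: 2530.10, shape2: 8.44}}
  u_rf_first_year: {value: 0.79, dist: {family: beta, shape1: 87.73, shape2: 24.17}}
  u_rf:            {value: 0.83, dist: {family: beta, shape1: 39.01, shape2: 8.33}}
  u_lr:            {value: 0.72, dist: {family: beta, shape1: 89.85, shape2: 34.60}}
  u_dr:            {value: 0.53, dist: {family: beta, shape1: 4.61,  shape2: 4.13}}
  u_chf:           {value: 0.71, dist: {family: beta, shape1: 72.38, shape2: 29.57}}
  u_aml:           {value: 0.26, dist: {family: beta, shape1: 9.13,  shape2: 25.98}}
  u_dr_terminal:   {value: 0.16, dist: {family: beta, shape1: 5.00,  shape2: 26.26}}

# The five shipped neoadjuvant-adjuvant strategies.  After any neoadjuvant
# regimen, patients with pathologic complete response (pCR) receive adjuvant
# trastuzumab (H); patients with residual disease receive the listed adjuvant
# regimen.  `residual_rr_dr` names the relative risk of distant recurrence
# applied to the residual branch (reference: residual disease on adjuvant H).
# Toxicity classes: ac (anthracycline-containing chemotherapy), non_ac
# (chemotherapy without anthracycline), no_chemo.
strategies:
  - id: 1
    name: "DDAC/THP -> H (all)"
    neoadjuvant: DDAC_THP
    pcr_adjuvant: H
    residual_adjuvant: H
    residual_rr_dr: H
    pcr_toxicity: ac
    residual_toxicity: ac
    residual_lr_reference: true   # residual disease on H is the LR reference group
  - id: 2
    name: "DDAC/THP -> T-DM1 (residual) / H (pCR)"
    neoadjuvant: DDAC_THP
    pcr_adjuvant: H
    residual_adjuvant: TDM1
    residual_rr_dr: TDM1
    pcr_toxicity: ac
    residual_toxicity: ac
  - id: 3
    name: "THP -> DDAC+T-DM1 (residual) / H (pCR)"
    neoadjuvant: THP
    pcr_adjuvant: H
    residual_adjuvant: DDAC_TDM1
    residual_rr_dr: DDAC_TDM1
    pcr_toxicity: non_ac
    residual_toxicity: ac
  - id: 4
    name: "HP -> DDAC/THP+T-DM1 (residual) / H (pCR)"
    neoadjuvant: HP
    pcr_adjuvant: H
    residual_adjuvant: DDACTHP_TDM1
    residual_rr_dr: DDACTHP_TDM1
    pcr_toxicity: no_chemo
    residual_toxicity: ac
  - id: 5
    name: "TCHP -> T-DM1 (residual) / H (pCR)"
    neoadjuvant: TCHP
    pcr_adjuvant: H_POST_TCHP
    residual_adjuvant: TDM1_POST_TCHP
    residual_rr_dr: TDM1
    pcr_toxicity: non_ac
    residual_toxicity: non_ac
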