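# Base-case inputs for the NVAF anticoagulation cost-effectiveness model.
# Spanish NHS perspective, costs in 2018 euros.
#
# Each uncertain scalar is written as {value, dsa: [low, high], psa: family}.
# "dsa" is the one-way (tornado) range; "psa" names the sampling family used
# in probabilistic sensitivity analysis (beta, gamma, lognormal).  Scalars
# without ranges are treated as fixed.

model:
  cycle_length_years: 0.25
  horizon_years: 30
  discount_rate: 0.03          # per annum, applied to costs and effects
  wtp_threshold: 22000         # euros per QALY
  half_cycle_correction: false
  rate_conversion: exponential # p = 1 - exp(-r t); "linear" available for audit
  # Event risk off anticoagulation relative to the VKA-treated baseline:
  # stroke risk roughly trebles when untreated (two-thirds relative risk
  # reduction on VKA), bleeding roughly halves, MI unchanged.
  off_treatment_risk_multiplier: {minor_is: 2.78, major_is: 2.78, mi: 1.0, gi: 0.5, ich: 0.5}
  discontinue_after_events: [major_is, ich]

cohort:
  entry_age: 73.4
  male_fraction: 0.517
  cha2ds2vasc_high_fraction: 0.822   # CHA2DS2-VASc >= 2; reporting metadata

# Baseline event rates in the VKA arm, events per 100 patient-years.
# Per-cycle probabilities are derived from these by 1 - exp(-r t).
clinical_rates:
  is:  {value: 1.11, dsa: [0.98, 1.27]}
  gi:  {value: 1.04, dsa: [0.90, 1.19]}
  ich: {value: 0.34, dsa: [0.29, 0.53]}
  mi:  {value: 0.77, dsa: [0.73, 0.82]}
  # Share of ischaemic strokes that are minor; chosen so the derived minor /
  # major 3-month probabilities reproduce 0.114% / 0.163%.
  minor_is_fraction: {value: 0.41}

# 3-month probabilities (VKA arm).  Base values are derived from the rates
# above; the entries below carry the printed uncertainty ranges used in the
# sensitivity analyses.
cycle_probabilities:
  minor_is: {dsa: [0.00100, 0.00130], psa: beta}
  major_is: {dsa: [0.00144, 0.00187], psa: beta}
  mi:       {dsa: [0.00181, 0.00205], psa: beta}
  gi:       {dsa: [0.00225, 0.00297], psa: beta}
  ich:      {dsa: [0.00072, 0.00132], psa: beta}

# 3-month probabilities of discontinuation, by time since initiation.
discontinuation:
  p_0_3m:   {value: 0.1500, dsa: [0.1419, 0.1581], psa: beta}
  p_3_6m:   {value: 0.1059, dsa: [0.0989, 0.1128], psa: beta}
  p_6_12m:  {value: 0.0823, dsa: [0.0761, 0.0885], psa: beta}
  p_12plus: {value: 0.0640, dsa: [0.0586, 0.0695], psa: beta}

# Treatment arms.  Hazard ratios are versus VKA; the ischaemic-stroke HR
# applies to both minor and major stroke.  Hazard-ratio uncertainty is
# sampled lognormally (the ranges are read as 95% CIs); GI HR > 1 rules out
# a literal [0,1] beta.  admin_cost_per_cycle covers INR monitoring (VKA) or
# routine administration visits (NOACs); it is not printed in the source
# tables and is calibrated by analysis/00_calibrate.py against the published
# lifetime administration cost totals.
treatments:
  vka:
    daily_drug_cost: 0.10
    admin_cost_per_cycle: 99.47        # calibrated
    switch_proportion: {value: 0.2580, dsa: [0.2193, 0.2967], psa: beta}
    hr:
      is: 1.0
      mi: 1.0
      gi: 1.0
      ich: 1.0
      discontinuation: 1.0
  rivaroxaban:
    daily_drug_cost: 1.79
    admin_cost_per_cycle: 46.84        # calibrated
    switch_proportion: {value: 0.2320, dsa: [0.1972, 0.2668], psa: beta}
    hr:
      is:  {value: 0.83, dsa: [0.75, 0.93], psa: lognormal}
      mi:  {value: 0.96, dsa: [0.80, 1.14], psa: lognormal}
      gi:  {value: 1.22, dsa: [1.12, 1.33], psa: lognormal}
      ich: {value: 0.68, dsa: [0.52, 0.90], psa: lognormal}
      discontinuation: {value: 0.62, dsa: [0.60, 0.65], psa: lognormal}
  dabigatran:
    daily_drug_cost: 1.79
    admin_cost_per_cycle: 48.21        # calibrated
    switch_proportion: {value: 0.3540, dsa: [0.3009, 0.4071], psa: beta}
    hr:
      is:  {value: 0.79, dsa: [0.65, 0.97], psa: lognormal}
      mi:  {value: 0.84, dsa: [0.71, 1.00], psa: lognormal}
      gi:  {value: 1.12, dsa: [1.02, 1.24], psa: lognormal}
      ich: {value: 0.45, dsa: [0.36, 0.58], psa: lognormal}
      discontinuation: {value: 0.91, dsa: [0.53, 1.24], psa: lognormal}
  apixaban:
    daily_drug_cost: 1.79
    admin_cost_per_cycle: 49.99        # calibrated
    switch_proportion: {value: 0.3670, dsa: [0.3120, 0.4221], psa: beta}
    hr:
      is:  {value: 1.01, dsa: [0.87, 1.17], psa: lognormal}
      mi:  1.00
      gi:  {value: 0.52, dsa: [0.38, 0.70], psa: lognormal}
      ich: {value: 0.41, dsa: [0.28, 0.60], psa: lognormal}
      discontinuation: {value: 1.08, dsa: [0.81, 1.45], psa: lognormal}

# In-hospital mortality per clinical event (acute case fatality) and
# per-cycle excess mortality in the post-event states.
mortality:
  acute_case_fatality:
    minor_is: {value: 0.0289, dsa: [0.0257, 0.0320], psa: beta}
    major_is: {value: 0.1260, dsa: [0.0940, 0.1570], psa: beta}
    mi:       {value: 0.0969, dsa: [0.0727, 0.1211], psa: beta}
    ich:      {value: 0.3885, dsa: [0.2914, 0.4856], psa: beta}
    gi:       {value: 0.0733, dsa: [0.0692, 0.0774], psa: beta}
  post_excess_per_cycle:
    post_major_is: {value: 0.0263, dsa: [0.0091, 0.1350], psa: beta}
    post_mi:       {value: 0.0268, dsa: [0.0000, 0.0675], psa: beta}
    post_ich:      {value: 0.0263, dsa: [0.0091, 0.1350], psa: beta}

utilities:
  stable_af:     {value: 0.73, dsa: [0.71, 0.75], psa: beta}
  minor_is:      {value: 0.73, dsa: [0.55, 0.91], psa: beta}
  major_is:      {value: 0.41, dsa: [0.31, 0.51], psa: beta}
  post_minor_is: {value: 0.76, dsa: [0.57, 0.95], psa: beta}
  post_major_is: {value: 0.56, dsa: [0.42, 0.70], psa: beta}
  mi:            {value: 0.66, dsa: [0.53, 0.79], psa: beta}
  post_mi:       {value: 0.73, dsa: [0.58, 0.88], psa: beta}
  ich:           {value: 0.56, dsa: [0.45, 0.67], psa: beta}
  post_ich:      {value: 0.67, dsa: [0.54, 0.80], psa: beta}
  gi:            {value: 0.70, dsa: [0.56, 0.84], psa: beta}

# Event management costs (euros, 2018).
costs:
  acute:
    minor_is: {value: 5258, dsa: [3953, 6572], psa: gamma}
    major_is: {value: 7208, dsa: [5406, 9010], psa: gamma}
    mi:       {value: 5174, dsa: [3880, 6467], psa: gamma}
    gi:       {value: 3579, dsa: [2685, 4474], psa: gamma}
    ich:      {value: 7793, dsa: [5845, 9741], psa: gamma}
  monthly_followup:
    minor_is: {value: 124,  dsa: [93, 156],     psa: gamma}
    major_is: {value: 2159, dsa: [1619, 2699],  psa: gamma}
    # The printed one-way range for MI follow-up does not bracket the mean;
    # it is kept verbatim and flagged.
    mi:       {value: 516,  dsa: [129, 215],    psa: gamma, allow_nonbracketing: true}
    bleeding: {value: 191,  dsa: [143, 238],    psa: gamma}
  rehabilitation:
    is:       {value: 3015, dsa: [2261, 3768], psa: gamma}
    bleeding: {value: 2874, dsa: [2155, 3592], psa: gamma}
  rehab_proportion:
    minor_is: {value: 0.050, dsa: [0.0425, 0.0575], psa: beta}
    major_is: {value: 0.374, dsa: [0.3179, 0.4301], psa: beta}
    gi:       {value: 0.106, dsa: [0.0901, 0.1219], psa: beta}
    ich:      {value: 0.450, dsa: [0.3825, 0.5175], psa: beta}

# Relative risk of ischaemic stroke by age band (reference 70-74).
age_stroke_rr:
  - {age_from: 55, rr: 0.667}
  - {age_from: 60, rr: 0.760}
  - {age_from: 65, rr: 0.854}
  - {age_from: 70, rr: 1.000}
  - {age_from: 75, rr: 1.146}
  - {age_from: 80, rr: 1.281}
  - {age_from: 85, rr: 1.480}
  - {age_from: 90, rr: 1.719}
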