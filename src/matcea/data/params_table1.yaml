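# Default model configuration: published input table for the maternal-care
# cost-effectiveness analysis (Kwara State, Nigeria; US$ 2012).
#
# Conventions
#   beta       : mean + sd (method of moments)
#   uniform    : min + max (point estimate = midpoint)
#   triangular : mean + min + max (mode derived as 3*mean - min - max),
#                or an explicit mode where the printed mean is too coarsely
#                rounded for the derivation to be feasible (daly_anaemia).
#   "name@scope" keys are scenario-specific variants.
#
# Calibrated structural quantities (facility shares for the no-ANC stratum,
# the insured ANC-stratum facility share, the sepsis calibration ratio, the
# standard-of-care hypertensive-prophylaxis coverage, the extended
# hypertensive-disorder sequela weight and the baseline healthy-life ledger
# constant) are reconstructions fitted once to the published cohort and
# cost-effectiveness tables; their derivations are documented in
# docs/methods.md.  They are not printed source values.

cohort_size: 10000

parameters:
  # ---- utilization --------------------------------------------------
  anc_access@soc:        {family: uniform, min: 0.6, max: 0.7}
  anc_access@kshi:       {family: uniform, min: 0.8, max: 0.9}
  facility_delivery_all@soc:  {family: uniform, min: 0.4, max: 0.6}
  facility_delivery_all@kshi: {family: uniform, min: 0.65, max: 0.7}
  eoc_if_facility@soc:   {family: uniform, min: 0.9, max: 0.95}
  eoc_if_facility@kshi:  {family: point, mean: 1.0}
  facility_if_anc:       {family: beta, mean: 0.96, sd: 0.03}
  home_if_anc:           {family: beta, mean: 0.05, sd: 0.03}
  eoc_if_home:           {family: beta, mean: 0.136, sd: 0.02}

  # ---- complication and outcome probabilities -----------------------
  p_pph:                 {family: beta, mean: 0.051, sd: 0.04}
  p_anaemia_pph:         {family: beta, mean: 0.12, sd: 0.01}
  p_death_pph:           {family: uniform, min: 0.028, max: 0.273}
  rr_pph_death_eoc:      {family: beta, mean: 0.34, sd: 0.19}
  rr_anaemia_eoc:        {family: beta, mean: 0.5, sd: 0.14}
  p_sepsis:              {family: triangular, mean: 0.017, min: 0.01, max: 0.03}
  p_infertility_sepsis:  {family: uniform, min: 0.05, max: 0.1}
  p_death_sepsis:        {family: uniform, min: 0.0, max: 0.727}
  rr_sepsis_hospital:    {family: triangular, mean: 0.54, min: 0.4, max: 0.65}
  p_ol:                  {family: beta, mean: 0.06, sd: 0.02}
  p_fistula_ol:          {family: beta, mean: 0.14, sd: 0.01}
  p_death_ol:            {family: beta, mean: 0.007, sd: 0.01}
  p_htd:                 {family: beta, mean: 0.085, sd: 0.04}
  p_death_htd:           {family: beta, mean: 0.083, sd: 0.02}
  rr_htd_anc:            {family: beta, mean: 0.41, sd: 0.08}

  # ---- unit costs (US$ 2012, provider perspective) ------------------
  cost_anc:                    {family: uniform, min: 12.4, max: 61.5}
  cost_delivery_uncomplicated: {family: uniform, min: 9.65, max: 27.2}
  cost_delivery_complicated:   {family: uniform, min: 46.7, max: 53.3}
  cost_fistula_treatment:      {family: uniform, min: 190.9, max: 382.7}
  cost_anaemia_treatment:      {family: uniform, min: 9.81, max: 13.79}
  # Annualised insurer administration + program management per enrolee;
  # min/max declare the one-way sensitivity bounds (+/- 50%).
  above_service_cost:          {family: point, mean: 24.1, min: 12.05, max: 36.15}

  # ---- per-event DALY values (discounted, no age weighting) ---------
  daly_death:       {family: triangular, mean: 23.43, min: 21.09, max: 25.77}
  daly_anaemia:     {family: triangular, min: 0.08, max: 0.09, mode: 0.09}
  daly_infertility: {family: triangular, mean: 0.1, min: 0.09, max: 0.11}
  daly_fistula:     {family: triangular, mean: 10.93, min: 9.84, max: 12.02}
  # Calibrated reconstruction: residual long-term morbidity per surviving
  # hypertensive-disorder case needed to reproduce the published scenario
  # DALY ledger (see docs/methods.md).
  daly_extended_htd: {family: point, mean: 21.33172296627711}

  # ---- accounting constants -----------------------------------------
  discount_rate:          {family: point, mean: 0.03, min: 0.0, max: 0.06}
  # Healthy life-years credited per woman in ledger-mode accounting;
  # calibrated to the published per-scenario DALY totals.
  baseline_healthy_life:  {family: point, mean: 38.13259922079239}

scenarios:
  soc:
    comparator: true
    noanc_facility_share: 0.0385864896656591
    anc_facility_share: null          # renormalize facility/home-given-ANC
    htd_prophylaxis_coverage: 0.2991026919242274
    sepsis_calibration: 1.1121778935561115
    above_service: false

  kshi:
    noanc_facility_share: 0.0769585785162109
    anc_facility_share: 0.9738340450473081
    htd_prophylaxis_coverage: 1.0
    sepsis_calibration: 1.1121778935561115
    above_service: true

  # Alternative base cases for the scenario analysis.  soc1 raises the
  # standard-of-care utilization to insured levels; soc2 raises standard-of-
  # care provider costs to literature (public-sector) levels and sets quality
  # indicators to their high bounds; soc3 combines both.  Literature cost
  # points are approximate reconstructions (docs/methods.md).
  soc1:
    fallback_scope: soc
    noanc_facility_share: 0.0769585785162109
    anc_facility_share: 0.9738340450473081
    htd_prophylaxis_coverage: 0.2991026919242274
    sepsis_calibration: 1.1121778935561115
    above_service: false
    overrides:
      anc_access: {family: uniform, min: 0.8, max: 0.9}

  soc2:
    fallback_scope: soc
    noanc_facility_share: 0.0385864896656591
    anc_facility_share: null
    htd_prophylaxis_coverage: 1.0
    sepsis_calibration: 1.1121778935561115
    above_service: false
    overrides:
      eoc_if_facility: {family: point, mean: 0.95}
      cost_anc: {family: point, mean: 65.0}
      cost_delivery_uncomplicated: {family: point, mean: 25.0}
      cost_delivery_complicated: {family: point, mean: 75.0}

  soc3:
    fallback_scope: soc
    noanc_facility_share: 0.0769585785162109
    anc_facility_share: 0.9738340450473081
    htd_prophylaxis_coverage: 1.0
    sepsis_calibration: 1.1121778935561115
    above_service: false
    overrides:
      anc_access: {family: uniform, min: 0.8, max: 0.9}
      eoc_if_facility: {family: point, mean: 0.95}
      cost_anc: {family: point, mean: 65.0}
      cost_delivery_uncomplicated: {family: point, mean: 25.0}
      cost_delivery_complicated: {family: point, mean: 75.0}
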