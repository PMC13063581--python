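# Default synthetic-cohort configuration.
#
# Marginals for age band, country of origin, condom use, sex partners,
# sexualized drug use and federal state transcribe the published cohort
# summary of the PrApp survey (proportions among PrEP-indicated cis-MSM,
# renormalized over observed categories; the published per-variable missing
# shares appear under missing_rate).  Variables the publication does not
# tabulate (per-pathogen diagnosis counts, household income options,
# household size, schooling, satisfaction, partner genders) carry plausible
# values for a German MSM online sample.  These are generator defaults, not
# assertions about the real data.
n_participants: 1458
seed: 0

covariate_marginals:
  age_band: {"18-29": 0.231, "30-39": 0.336, "40-49": 0.276, "50-80": 0.157}
  country_of_origin: {"Germany": 0.812, "Outside Germany": 0.188}
  condom_use_category: {"0%": 0.268, "25%": 0.315, "50%": 0.178, "75%": 0.112, ">95%": 0.127}
  n_sex_partners_6m_category: {"0": 0.007, "1": 0.017, "2-3": 0.178, "4-5": 0.184, "6-10": 0.225, "11-20": 0.158, ">20": 0.231}
  sdu_6m: {"yes": 0.232, "no": 0.768}
  syphilis_dx_12m: {"0": 0.93, "1": 0.06, "2+": 0.01}
  gonorrhea_dx_12m: {"0": 0.82, "1": 0.14, "2+": 0.04}
  chlamydia_dx_12m: {"0": 0.80, "1": 0.15, "2+": 0.05}
  hepatitis_c_dx_12m: {"0": 0.985, "1": 0.012, "2+": 0.003}
  hiv_status_confirmed_negative: {"yes": 0.90, "no": 0.10}
  gender_identity: {"male": 0.97, "female": 0.01, "non-binary": 0.02}
  sex_assigned_at_birth: {"male": 0.99, "female": 0.01}
  urban_rural: {"urban": 0.75, "rural": 0.25}
  satisfaction_sex_life: {"content": 0.60, "discontent": 0.25, "sex_does_not_matter": 0.15}
  school_qualification: {"no_qualification": 0.01, "secondary_8_9": 0.08, "secondary_10": 0.21, "a_levels": 0.70}
  household_size: {1: 0.42, 2: 0.40, 3: 0.10, 4: 0.06, 5: 0.02}
  household_income_category: {"<500": 0.03, "500-<1000": 0.07, "1000-<1500": 0.10, "1500-<2000": 0.12, "2000-<2500": 0.13, "2500-<3000": 0.13, "3000-<3500": 0.12, "3500-<4000": 0.10, "4000-<4500": 0.09, "4500-<5000": 0.07, ">5000": 0.04}
  prior_wave_participation: {"yes": 0.02, "no": 0.98}
  survey_completed: {"yes": 0.97, "no": 0.03}
  partner_male: {"yes": 0.98, "no": 0.02}
  partner_female: {"yes": 0.07, "no": 0.93}
  partner_non-binary: {"yes": 0.03, "no": 0.97}
  federal_state:
    "Baden-Wuerttemberg": 0.0811
    "Bavaria": 0.1495
    "Berlin": 0.1989
    "Brandenburg": 0.0141
    "Bremen": 0.0063
    "Hamburg": 0.0550
    "Hesse": 0.0945
    "Mecklenburg Western Pomerania": 0.0134
    "Lower Saxony": 0.0557
    "North Rhine-Westphalia": 0.2123
    "Rhineland-Palatinate": 0.0402
    "Saarland": 0.0085
    "Saxony": 0.0402
    "Saxony-Anhalt": 0.0106
    "Schleswig-Holstein": 0.0113
    "Thuringia": 0.0084

# Log-odds model for being a current PrEP user (vs never-user); effect
# directions and sizes mirror the multivariable associations the study
# reports (fewer partners, sexualized drug use, young age, discontent and
# female partners lower uptake; a chlamydia history raises it).
outcome_model:
  intercept: 0.87
  effects:
    n_sex_partners_6m_category: {"1": -0.27, "2-3": -0.77, "4-5": -0.31, "11-20": 0.26}
    sdu_6m: {"yes": -0.23}
    chlamydia_dx_12m: {"1": 0.28}
    age_band: {"18-29": -0.24}
    satisfaction_sex_life: {"discontent": -0.31}
    partner_female: {"yes": -0.30}

# Citation probabilities for reasons of non-use, stratified by sexualized
# drug use; values follow the published reason table's SDU vs non-SDU split.
reason_stratum_variable: sdu_6m
reason_probs:
  risk_too_low: {"yes": 0.328, "default": 0.249}
  no_doctor: {"yes": 0.209, "default": 0.183}
  effort_doctor_visits: {"yes": 0.224, "default": 0.362}
  discuss_sex_life: {"yes": 0.209, "default": 0.276}
  negative_reactions: {"yes": 0.015, "default": 0.083}
  side_effects: {"yes": 0.552, "default": 0.568}
  daily_pill: {"yes": 0.343, "default": 0.169}
  medical_reasons: {"yes": 0.0, "default": 0.013}

missing_rate:
  condom_use_category: 0.016
  n_sex_partners_6m_category: 0.011
  sdu_6m: 0.021
  syphilis_dx_12m: 0.40
  gonorrhea_dx_12m: 0.40
  chlamydia_dx_12m: 0.40
  hepatitis_c_dx_12m: 0.40
  federal_state: 0.027
  household_income_category: 0.043
  urban_rural: 0.02
  satisfaction_sex_life: 0.03
  school_qualification: 0.02

former_rate: 0.034
unspecified_prep_rate: 0.017
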