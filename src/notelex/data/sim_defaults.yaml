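# Default generating parameters for the synthetic study.
#
# Covariate marginals follow the descriptive statistics of the study
# population being emulated (patient-level category percentages and
# encounter-level means); true_beta holds the generating conditional
# log-odds effects (natural logs of the adjusted odds ratios); the
# baseline intercept is calibrated so that about 8.2% of simulated
# patients have at least one negative note under these defaults.

n_patients: 2000

covariate_marginals:
  race:
    white: 0.297
    black: 0.606
    hispanic_latino: 0.062
    other: 0.035
  age_band:
    "0-17": 0.119
    "18-29": 0.134
    "30-44": 0.168
    "45-64": 0.303
    "65+": 0.276
  sex:
    male: 0.440
    female: 0.560
  married:
    married: 0.322
    not_married: 0.678
  english_primary:
    english: 0.978
    not_english: 0.022
  insurance:
    medicaid: 0.322
    medicare: 0.327
    private: 0.351
  covid_positive:
    positive: 0.082
    negative: 0.918

encounter:
  location:
    inpatient: 0.466
    outpatient: 0.518
    ed: 0.016
  after_cutoff_prob: 0.807
  length_days_mean: 4.4
  cci_mean: 1.4
  # encounters per patient = 1 + Poisson(lambda); mean 1.795 encounters
  encounters_per_patient_lambda: 0.795
  # notes per encounter = 1 + Poisson(lambda); mean 1.21 notes
  notes_per_encounter_lambda: 0.21

# Conditional log-odds effects: ln of the adjusted odds ratios.
true_beta:
  race_black: 0.93216
  race_hispanic_latino: 0.41211
  race_other: 0.06766
  age_0_17: -0.21072
  age_18_29: -0.13926
  age_30_44: 0.11333
  age_45_64: 0.33647
  sex_female: -0.27444
  not_married: 0.75142
  not_english: -0.26136
  ins_medicaid: 0.97833
  ins_medicare: 0.73237
  loc_outpatient: -0.99425
  loc_ed: -0.35667
  cci: 0.10436
  length_days: 0.0
  covid_positive: -0.12783
  after_cutoff: -0.19845

sigma2_patient: 1.0
sigma2_encounter: 0.5
baseline_intercept: -5.13

distractor_positive_rate: 0.30
distractor_ooc_rate: 0.10

missing_race: 0
missing_covariates: 0

noise_token_dropout: 0.05
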