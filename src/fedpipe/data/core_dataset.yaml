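# Default harmonized variable dictionary: the printed subset of the
# "COVID-19 in MS" core data set. Users extend this document for the
# unpublished remainder of the variable list.
version: "core-1.0"
variables:
  - name: covid19_date_reporting
    format: date
  - name: covid19_suspected_onset
    format: date
    depends_on: [ms_onset_date, ms_diagnosis_date]
  - name: covid19_confirmed_case
    format: single_choice
    choices: ["yes", "no"]
  - name: covid19_has_symptoms
    format: single_choice
    choices: ["yes", "no"]
    depends_on:
      - covid19_sympt_fever
      - covid19_sympt_dry_cough
      - covid19_sympt_fatigue
      - covid19_sympt_pain
      - covid19_sympt_sore_throat
      - covid19_sympt_shortness_breath
      - covid19_sympt_nasal_congestion
      - covid19_sympt_loss_smell_taste
      - covid19_sympt_pneumonia
  - name: covid19_sympt_fever
    format: single_choice
    choices: ["yes", "no"]
    depends_on: [covid19_has_symptoms]
  - name: covid19_sympt_dry_cough
    format: single_choice
    choices: ["yes", "no"]
    depends_on: [covid19_has_symptoms]
  - name: covid19_sympt_fatigue
    format: single_choice
    choices: ["yes", "no"]
    depends_on: [covid19_has_symptoms]
  - name: covid19_sympt_pain
    format: single_choice
    choices: ["yes", "no"]
    depends_on: [covid19_has_symptoms]
  - name: covid19_sympt_sore_throat
    format: single_choice
    choices: ["yes", "no"]
    depends_on: [covid19_has_symptoms]
  - name: covid19_sympt_shortness_breath
    format: single_choice
    choices: ["yes", "no"]
    depends_on: [covid19_has_symptoms]
  - name: covid19_sympt_nasal_congestion
    format: single_choice
    choices: ["yes", "no"]
    depends_on: [covid19_has_symptoms]
  - name: covid19_sympt_loss_smell_taste
    format: single_choice
    choices: ["yes", "no"]
    depends_on: [covid19_has_symptoms]
  - name: covid19_sympt_pneumonia
    format: single_choice
    choices: ["yes", "no"]
    depends_on: [covid19_has_symptoms]
  - name: covid19_admission_hospital
    format: single_choice
    choices: ["yes", "no"]
    depends_on: [covid19_confirmed_case]
  - name: covid19_icu_admission
    format: single_choice
    choices: ["yes", "no"]
  - name: covid19_ventilation
    format: single_choice
    choices: ["yes", "no"]
  - name: covid19_death
    format: single_choice
    choices: ["yes", "no"]
  - name: age_years
    format: integer
  - name: sex
    format: single_choice
    choices: [male, female]
  - name: ms_onset_date
    format: date
    depends_on: [ms_diagnosis_date, covid19_suspected_onset]
  - name: ms_diagnosis_date
    format: date
  - name: ms_type
    format: single_choice
    choices: [relapsing_remitting, progressive]
  - name: edss_value
    format: number
  - name: current_dmt
    format: single_choice
    choices: ["yes", "no"]
    depends_on: [type_dmt, type_dmt_other]
  - name: type_dmt
    format: single_choice
    choices:
      - untreated
      - alemtuzumab
      - cladribine
      - dimethyl_fumarate
      - fingolimod
      - glatiramer_acetate
      - interferon
      - natalizumab
      - ocrelizumab
      - rituximab
      - teriflunomide
      - other
  - name: type_dmt_other
    format: text
  - name: has_comorbidities
    format: single_choice
    choices: ["yes", "no"]
    depends_on:
      - com_hypertension
      - com_diabetes
      - com_cardiovascular_disease
      - com_chronic_lung_disease
      - com_obesity
  - name: com_hypertension
    format: single_choice
    choices: ["yes", "no"]
  - name: com_diabetes
    format: single_choice
    choices: ["yes", "no"]
  - name: com_cardiovascular_disease
    format: single_choice
    choices: ["yes", "no"]
  - name: com_chronic_lung_disease
    format: single_choice
    choices: ["yes", "no"]
  - name: com_obesity
    format: single_choice
    choices: ["yes", "no"]
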