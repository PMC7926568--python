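- cadre_id: midwife
  baseline_stock: 8600.0
  attrition_rate: 0.045
  participation_rate: 0.93
  awt:
    possible_working_days: 260.0
    public_holidays: 9.0
    annual_leave: 21.0
    sick_leave: 5.0
    other_absences: 4.0
    hours_per_day: 8.0
  support_activities:
  - name: handing_over
    sas: 0.125
  - name: clinical_unit_meetings
    sas: 0.05
  pipeline:
    enrolment_by_year:
      2017: 1500.0
      2018: 1500.0
      2019: 1500.0
      2020: 1500.0
      2021: 1500.0
      2022: 1500.0
      2023: 1500.0
      2024: 1500.0
      2025: 1500.0
      2026: 1500.0
      2027: 1500.0
    dropout_rate: 0.08
    training_duration: 3
    pass_rate: 0.92
    immigration_by_year: {}
  baseline_income: 10700.0
  income_inflation: 0.08
- cadre_id: obstetrician_gynaecologist
  baseline_stock: 190.0
  attrition_rate: 0.03
  participation_rate: 1.0
  awt:
    possible_working_days: 260.0
    public_holidays: 9.0
    annual_leave: 21.0
    sick_leave: 5.0
    other_absences: 4.0
    hours_per_day: 8.0
  support_activities:
  - name: clinical_unit_meetings
    sas: 0.15
  pipeline:
    enrolment_by_year:
      2016: 38.0
      2017: 38.0
      2018: 38.0
      2019: 38.0
      2020: 38.0
      2021: 38.0
      2022: 38.0
      2023: 38.0
      2024: 38.0
      2025: 38.0
      2026: 38.0
    dropout_rate: 0.05
    training_duration: 4
    pass_rate: 0.9
    immigration_by_year:
      2020: 2.0
      2021: 2.0
      2022: 2.0
      2023: 2.0
      2024: 2.0
      2025: 2.0
      2026: 2.0
      2027: 2.0
      2028: 2.0
      2029: 2.0
      2030: 2.0
  baseline_income: 19500.0
  income_inflation: 0.08
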