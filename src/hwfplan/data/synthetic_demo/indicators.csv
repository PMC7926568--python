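indicator_id,age_cohorts,genders,locations,baseline_year,baseline_value,second_year,second_value,rate_of_change
pregnancy_rate,15-49,female,,2020,0.14,,,0.008
complicated_delivery_rate,15-49,female,,2007,0.018,2017,0.024,
newborn_care_need,0-1,,,2020,0.85,,,0.005
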