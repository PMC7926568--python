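service_id,indicator_id,frequency_per_person_in_need,service_standard,work_division
anc_visit,pregnancy_rate,8.0,primary:0.25;tertiary:0.33,midwife:0.95;obstetrician_gynaecologist:0.05
normal_delivery,pregnancy_rate,0.9,primary:10.0;tertiary:12.0,midwife:0.97;obstetrician_gynaecologist:0.03
obstetric_intervention,complicated_delivery_rate,1.0,primary:4.0;tertiary:5.0,midwife:0.2;obstetrician_gynaecologist:0.8
postnatal_visit,newborn_care_need,3.0,primary:0.33;tertiary:0.4,midwife:1.0
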