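cadre_id,year,cost_of_need,cost_of_supply
midwife,2020,176988192.56,118759613
midwife,2025,285949683.80,293467630
midwife,2030,433445908.15,441711580
obstetrician_gynaecologist,2020,14278392.77,3454061
obstetrician_gynaecologist,2025,23090373.91,11214559
obstetrician_gynaecologist,2030,34820936.99,20921755
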