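cadre_id,activity,measurement,sas
midwife,handing_over,1 h per day,0.125
midwife,clinical_unit_meetings,2 h per week,0.05
obstetrician_gynaecologist,clinical_unit_meetings,6 h per week,0.15
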