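cadre_id,year,need
midwife,2020,16462
midwife,2021,16997
midwife,2022,17556
midwife,2023,18139
midwife,2024,18749
midwife,2025,19409
midwife,2026,20076
midwife,2027,20774
midwife,2028,21504
midwife,2029,22268
midwife,2030,23161
obstetrician_gynaecologist,2020,723
obstetrician_gynaecologist,2021,747
obstetrician_gynaecologist,2022,772
obstetrician_gynaecologist,2023,798
obstetrician_gynaecologist,2024,825
obstetrician_gynaecologist,2025,854
obstetrician_gynaecologist,2026,883
obstetrician_gynaecologist,2027,913
obstetrician_gynaecologist,2028,945
obstetrician_gynaecologist,2029,977
obstetrician_gynaecologist,2030,1013
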