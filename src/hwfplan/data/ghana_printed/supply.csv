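cadre_id,year,supply
midwife,2020,11930
midwife,2021,14057
midwife,2022,15878
midwife,2023,17438
midwife,2024,18775
midwife,2025,19919
midwife,2026,20900
midwife,2027,21739
midwife,2028,22459
midwife,2029,23075
midwife,2030,23602
obstetrician_gynaecologist,2020,189
obstetrician_gynaecologist,2021,216
obstetrician_gynaecologist,2022,242
obstetrician_gynaecologist,2023,266
obstetrician_gynaecologist,2024,290
obstetrician_gynaecologist,2025,313
obstetrician_gynaecologist,2026,335
obstetrician_gynaecologist,2027,356
obstetrician_gynaecologist,2028,377
obstetrician_gynaecologist,2029,396
obstetrician_gynaecologist,2030,415
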