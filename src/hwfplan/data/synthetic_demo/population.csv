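age_cohort,gender,location,year,count
15-49,female,rural,2020,3200000.0
15-49,female,rural,2021,3267200.0
15-49,female,rural,2022,3335811.2
15-49,female,rural,2023,3405863.2
15-49,female,rural,2024,3477386.4
15-49,female,rural,2025,3550411.5
15-49,female,rural,2026,3624970.1
15-49,female,rural,2027,3701094.5
15-49,female,rural,2028,3778817.5
15-49,female,rural,2029,3858172.6
15-49,female,rural,2030,3939194.3
15-49,female,urban,2020,4100000.0
15-49,female,urban,2021,4206600.0
15-49,female,urban,2022,4315971.6
15-49,female,urban,2023,4428186.9
15-49,female,urban,2024,4543319.7
15-49,female,urban,2025,4661446.0
15-49,female,urban,2026,4782643.6
15-49,female,urban,2027,4906992.4
15-49,female,urban,2028,5034574.2
15-49,female,urban,2029,5165473.1
15-49,female,urban,2030,5299775.4
0-1,all,rural,2020,420000.0
0-1,all,rural,2021,427560.0
0-1,all,rural,2022,435256.1
0-1,all,rural,2023,443090.7
0-1,all,rural,2024,451066.3
0-1,all,rural,2025,459185.5
0-1,all,rural,2026,467450.9
0-1,all,rural,2027,475865.0
0-1,all,rural,2028,484430.5
0-1,all,rural,2029,493150.3
0-1,all,rural,2030,502027.0
0-1,all,urban,2020,480000.0
0-1,all,urban,2021,489600.0
0-1,all,urban,2022,499392.0
0-1,all,urban,2023,509379.8
0-1,all,urban,2024,519567.4
0-1,all,urban,2025,529958.8
0-1,all,urban,2026,540558.0
0-1,all,urban,2027,551369.1
0-1,all,urban,2028,562396.5
0-1,all,urban,2029,573644.4
0-1,all,urban,2030,585117.3
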