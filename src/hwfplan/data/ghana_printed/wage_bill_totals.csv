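year,cost_of_need_total,cost_of_supply_total
2020,191266585.33,122213674.52
2025,309040058,304682188
2030,468266845,462633335
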