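label,require_active,require_inactive,priority
M2d,IL10_out VEGF_out,IL12_out,80
M2b,IL10_out IL6_out,,70
M2a,IL10_out STAT6,,60
M2c,IL10_out STAT3_s,,50
M2,IL10_out,,40
M2,VEGF_out,,40
M1,IL12_out,,30
il6,IL6_out,IL12_out IL10_out VEGF_out,20
M0,,,0
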