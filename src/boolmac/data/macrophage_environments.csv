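name,present
pro-M1,IFNG_e GMCSF_e LPS_e
pro-M2a,IL4_e
pro-M2b,LPS_e IC_e IL1B_e
pro-M2c,IL10_e
pro-M2d,IC_e IL4_e IL10_e
mixed,LPS_e IFNG_e IL4_e
free,
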