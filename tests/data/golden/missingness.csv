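variable,n_missing,pct_missing
ethnicity,12,11%
smoking,12,11%
lsoa_address,1,0.9%
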