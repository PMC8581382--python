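variable,stratum,category,count,pct,ci_low,ci_high,flag
smoking,BOTH,CURRENT,8,15.384615,8.007685,27.524085,
smoking,BOTH,FORMER,25,48.076923,35.104114,61.314317,
smoking,BOTH,MISSING,8,,,,
smoking,BOTH,NEVER,19,36.538462,24.800700,50.128322,
smoking,SPECIALIST_ONLY,CURRENT,7,29.166667,14.914648,49.167694,
smoking,SPECIALIST_ONLY,FORMER,12,50.000000,31.427426,68.572574,
smoking,SPECIALIST_ONLY,MISSING,3,,,,
smoking,SPECIALIST_ONLY,NEVER,5,20.833333,9.244825,40.470453,
smoking,PRIMARY_ONLY,CURRENT,8,42.105263,23.141891,63.724096,+
smoking,PRIMARY_ONLY,FORMER,7,36.842105,19.149513,58.960467,
smoking,PRIMARY_ONLY,MISSING,1,,,,
smoking,PRIMARY_ONLY,NEVER,4,21.052632,8.507677,43.334278,
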