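variable,stratum,category,count,pct,ci_low,ci_high,flag
ethnicity6,BOTH,ASIAN,2,3.636364,1.002954,12.323464,
ethnicity6,BOTH,BLACK,16,29.090909,18.771194,42.140720,
ethnicity6,BOTH,MISSING,5,,,,
ethnicity6,BOTH,MIXED,0,0.000000,0.000000,6.528490,
ethnicity6,BOTH,OTHER,1,1.818182,0.321678,9.605776,
ethnicity6,BOTH,WHITE_BRITISH,26,47.272727,34.693098,60.208456,
ethnicity6,BOTH,WHITE_NON_BRITISH,10,18.181818,10.187670,30.330460,
ethnicity6,SPECIALIST_ONLY,ASIAN,0,0.000000,0.000000,13.797620,
ethnicity6,SPECIALIST_ONLY,BLACK,7,29.166667,14.914648,49.167694,
ethnicity6,SPECIALIST_ONLY,MISSING,3,,,,
ethnicity6,SPECIALIST_ONLY,MIXED,0,0.000000,0.000000,13.797620,
ethnicity6,SPECIALIST_ONLY,OTHER,0,0.000000,0.000000,13.797620,
ethnicity6,SPECIALIST_ONLY,WHITE_BRITISH,13,54.166667,35.074865,72.108666,
ethnicity6,SPECIALIST_ONLY,WHITE_NON_BRITISH,4,16.666667,6.678676,35.853071,
ethnicity6,PRIMARY_ONLY,ASIAN,0,0.000000,0.000000,19.360768,
ethnicity6,PRIMARY_ONLY,BLACK,2,12.500000,3.497749,36.022827,
ethnicity6,PRIMARY_ONLY,MISSING,4,,,,
ethnicity6,PRIMARY_ONLY,MIXED,1,6.250000,1.111934,28.328738,+
ethnicity6,PRIMARY_ONLY,OTHER,0,0.000000,0.000000,19.360768,
ethnicity6,PRIMARY_ONLY,WHITE_BRITISH,9,56.250000,33.178556,76.901348,
ethnicity6,PRIMARY_ONLY,WHITE_NON_BRITISH,4,25.000000,10.182067,49.498317,
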