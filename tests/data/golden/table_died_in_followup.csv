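variable,stratum,category,count,pct,ci_low,ci_high,flag
died_in_followup,BOTH,False,48,80.000000,68.218194,88.171495,
died_in_followup,BOTH,True,12,20.000000,11.828505,31.781806,
died_in_followup,SPECIALIST_ONLY,False,20,74.074074,55.321429,86.829625,
died_in_followup,SPECIALIST_ONLY,True,7,25.925926,13.170375,44.678571,
died_in_followup,PRIMARY_ONLY,False,17,85.000000,63.958114,94.763125,
died_in_followup,PRIMARY_ONLY,True,3,15.000000,5.236875,36.041886,
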