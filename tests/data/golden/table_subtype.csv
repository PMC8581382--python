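variable,stratum,category,count,pct,ci_low,ci_high,flag
subtype,BOTH,ALZHEIMERS_MIXED,38,67.857143,54.822640,78.599005,
subtype,BOTH,OTHER_SPECIFIED,1,1.785714,0.315921,9.445637,
subtype,BOTH,UNSPECIFIED,4,,,,
subtype,BOTH,VASCULAR,17,30.357143,19.900325,43.335865,
subtype,SPECIALIST_ONLY,ALZHEIMERS_MIXED,20,76.923077,57.948446,88.966151,
subtype,SPECIALIST_ONLY,OTHER_SPECIFIED,0,0.000000,0.000000,12.872892,
subtype,SPECIALIST_ONLY,UNSPECIFIED,1,,,,
subtype,SPECIALIST_ONLY,VASCULAR,6,23.076923,11.033849,42.051554,
subtype,PRIMARY_ONLY,ALZHEIMERS_MIXED,10,62.500000,38.641041,81.518767,
subtype,PRIMARY_ONLY,OTHER_SPECIFIED,1,6.250000,1.111934,28.328738,
subtype,PRIMARY_ONLY,UNSPECIFIED,4,,,,
subtype,PRIMARY_ONLY,VASCULAR,5,31.250000,14.164644,55.595644,
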