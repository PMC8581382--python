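variable,stratum,category,count,pct,ci_low,ci_high,flag
age_group,BOTH,65_74,24,40.000000,28.569491,52.633947,
age_group,BOTH,75_84,16,26.666667,17.132640,39.008713,
age_group,BOTH,85_PLUS,20,33.333333,22.729262,45.943134,
age_group,SPECIALIST_ONLY,65_74,5,18.518519,8.180707,36.698684,-
age_group,SPECIALIST_ONLY,75_84,11,40.740741,24.514757,59.273299,
age_group,SPECIALIST_ONLY,85_PLUS,11,40.740741,24.514757,59.273299,
age_group,PRIMARY_ONLY,65_74,5,25.000000,11.186170,46.870088,
age_group,PRIMARY_ONLY,75_84,10,50.000000,29.929801,70.070199,+
age_group,PRIMARY_ONLY,85_PLUS,5,25.000000,11.186170,46.870088,
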