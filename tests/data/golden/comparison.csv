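characteristic,x1,n1,x2,n2,pr,ci_low,ci_high
age_85_plus,31,87,25,80,1.140230,0.741296,1.753853
female,52,87,47,80,1.017364,0.790850,1.308755
white_british,39,87,35,80,1.024631,0.728785,1.440572
charlson_high,13,87,12,80,0.996169,0.483195,2.053728
consult_high,41,87,40,80,0.942529,0.689678,1.288081
care_home,6,87,7,80,0.788177,0.276557,2.246276
died_in_followup,19,87,15,80,1.164751,0.635998,2.133096
alzheimers_mixed,58,87,48,80,1.111111,0.880548,1.402045
medicated,11,53,12,52,0.899371,0.436381,1.853584
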