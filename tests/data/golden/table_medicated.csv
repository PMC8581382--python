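variable,stratum,category,count,pct,ci_low,ci_high,flag
medicated,BOTH,False,44,73.333333,60.991287,82.867360,
medicated,BOTH,True,16,26.666667,17.132640,39.008713,
medicated,SPECIALIST_ONLY,False,24,88.888889,71.942199,96.147965,
medicated,SPECIALIST_ONLY,True,3,11.111111,3.852035,28.057801,
medicated,PRIMARY_ONLY,False,15,75.000000,53.129912,88.813830,
medicated,PRIMARY_ONLY,True,5,25.000000,11.186170,46.870088,
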