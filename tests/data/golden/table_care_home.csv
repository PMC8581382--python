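variable,stratum,category,count,pct,ci_low,ci_high,flag
care_home,BOTH,False,55,91.666667,81.931058,96.387954,
care_home,BOTH,True,5,8.333333,3.612046,18.068942,
care_home,SPECIALIST_ONLY,False,26,96.296296,81.716534,99.343185,
care_home,SPECIALIST_ONLY,True,1,3.703704,0.656815,18.283466,
care_home,PRIMARY_ONLY,False,18,90.000000,69.896635,97.213352,
care_home,PRIMARY_ONLY,True,2,10.000000,2.786648,30.103365,
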