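variable,stratum,category,count,pct,ci_low,ci_high,flag
sex,BOTH,F,35,58.333333,45.728081,69.935721,
sex,BOTH,M,25,41.666667,30.064279,54.271919,
sex,SPECIALIST_ONLY,F,17,62.962963,44.229234,78.467487,
sex,SPECIALIST_ONLY,M,10,37.037037,21.532513,55.770766,
sex,PRIMARY_ONLY,F,12,60.000000,38.658150,78.119347,
sex,PRIMARY_ONLY,M,8,40.000000,21.880653,61.341850,
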