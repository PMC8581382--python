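variable,stratum,category,count,pct,ci_low,ci_high,flag
consult_cat,BOTH,ABOVE_AVERAGE,29,48.333333,36.175050,60.692190,
consult_cat,BOTH,AVERAGE_OR_LESS,31,51.666667,39.307810,63.824950,
consult_cat,SPECIALIST_ONLY,ABOVE_AVERAGE,12,44.444444,27.585858,62.686975,
consult_cat,SPECIALIST_ONLY,AVERAGE_OR_LESS,15,55.555556,37.313025,72.414142,
consult_cat,PRIMARY_ONLY,ABOVE_AVERAGE,11,55.000000,34.208534,74.180214,
consult_cat,PRIMARY_ONLY,AVERAGE_OR_LESS,9,45.000000,25.819786,65.791466,
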