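variable,stratum,category,count,pct,ci_low,ci_high,flag
imd_q1,BOTH,False,56,93.333333,84.074643,97.377130,
imd_q1,BOTH,MISSING,0,,,,
imd_q1,BOTH,True,4,6.666667,2.622870,15.925357,
imd_q1,SPECIALIST_ONLY,False,25,96.153846,81.107221,99.317802,
imd_q1,SPECIALIST_ONLY,MISSING,1,,,,
imd_q1,SPECIALIST_ONLY,True,1,3.846154,0.682198,18.892779,
imd_q1,PRIMARY_ONLY,False,14,70.000000,48.102718,85.452276,-
imd_q1,PRIMARY_ONLY,MISSING,0,,,,
imd_q1,PRIMARY_ONLY,True,6,30.000000,14.547724,51.897282,+
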