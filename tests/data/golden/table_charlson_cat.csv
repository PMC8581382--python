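variable,stratum,category,count,pct,ci_low,ci_high,flag
charlson_cat,BOTH,0,20,33.333333,22.729262,45.943134,
charlson_cat,BOTH,1,10,16.666667,9.313177,28.031613,
charlson_cat,BOTH,2_3,21,35.000000,24.167774,47.637381,
charlson_cat,BOTH,4_5,6,10.000000,4.664283,20.149465,
charlson_cat,BOTH,6_PLUS,3,5.000000,1.714950,13.700516,
charlson_cat,SPECIALIST_ONLY,0,10,37.037037,21.532513,55.770766,
charlson_cat,SPECIALIST_ONLY,1,6,22.222222,10.607239,40.756929,
charlson_cat,SPECIALIST_ONLY,2_3,7,25.925926,13.170375,44.678571,
charlson_cat,SPECIALIST_ONLY,4_5,3,11.111111,3.852035,28.057801,
charlson_cat,SPECIALIST_ONLY,6_PLUS,1,3.703704,0.656815,18.283466,
charlson_cat,PRIMARY_ONLY,0,6,30.000000,14.547724,51.897282,
charlson_cat,PRIMARY_ONLY,1,3,15.000000,5.236875,36.041886,
charlson_cat,PRIMARY_ONLY,2_3,8,40.000000,21.880653,61.341850,
charlson_cat,PRIMARY_ONLY,4_5,3,15.000000,5.236875,36.041886,
charlson_cat,PRIMARY_ONLY,6_PLUS,0,0.000000,0.000000,16.112516,
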