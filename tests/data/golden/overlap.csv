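n_primary,n_specialist,n_both,n_union,pct_both_of_union,pct_overlap_of_primary,pct_overlap_of_specialist,restriction
80,87,60,107,56.074766355140184,75.0,68.96551724137932,NONE
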