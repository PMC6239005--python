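sex,age_min_yr,age_max_yr,coefficient
male,8,10,0.768
male,10,12,0.762
female,8,10,0.776
female,10,12,0.770
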