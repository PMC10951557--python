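,best_model,pseudo_r2,k,in_best
leaf_area,mean_temp,37.88510282603487,19,mean_temp
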