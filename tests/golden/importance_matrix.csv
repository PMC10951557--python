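,leaf_area
mean_temp,0.424303720821
mean_precip,0.170916101377
temp_var,0.127822959903
precip_var,0.145406981152
temp_range,0.152206210298
precip_range,0.150436116431
max_seasonal_precip,0.132749582564
min_seasonal_precip,0.198939684636
vpd,0.23531524918
max_drought_dur,0.166743043362
max_heatwave_dur,0.220309104192
max_dryspell_dur,0.293942635212
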