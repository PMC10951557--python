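trait,moderator,k,slope,se,p,pseudo_r2,tau2,intercept,intercept_p,intercept_sig
leaf_area,mean_temp,19,0.0533733608226,0.0253568838088,0.0353011945635,37.885102826,0.00423340865481,-0.0237070739906,0.519482684148,False
leaf_area,mean_precip,19,-0.0697020569012,0.0705820828142,0.323381962507,0,0.00694183450461,0.0347840882472,0.213247753154,False
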