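,mean_temp,mean_precip,temp_var,precip_var,temp_range,precip_range,max_seasonal_precip,min_seasonal_precip,vpd,max_drought_dur,max_heatwave_dur,max_dryspell_dur
mean_temp,1,-0.151420337212,-0.0777855353805,0.212920943536,0.290954162912,-0.589354810783,-0.204024761682,-0.111409820033,0.858763671082,-0.107639288739,-0.502297713001,0.111949517229
mean_precip,-0.151420337212,1,0.0233717942287,-0.606855012214,0.0640337885473,0.250419828508,0.197584421381,0.282170276239,-0.265922003147,-0.249863845844,0.416670716312,0.0985966180369
temp_var,-0.0777855353805,0.0233717942287,1,-0.371938599041,0.512888141449,-0.279055042521,-0.375820655994,0.184298996585,-0.160097430008,0.038780175323,-0.210774761618,-0.105552704654
precip_var,0.212920943536,-0.606855012214,-0.371938599041,1,-0.0668129480488,0.204825261549,0.194923069665,-0.13241350396,0.471594752931,0.206035945168,-0.32872212553,0.127870208118
temp_range,0.290954162912,0.0640337885473,0.512888141449,-0.0668129480488,1,-0.156270214623,-0.216267548274,0.200536245467,0.0974436376031,-0.344888070258,-0.314937217853,0.220607708053
precip_range,-0.589354810783,0.250419828508,-0.279055042521,0.204825261549,-0.156270214623,1,0.530788907211,0.312877267721,-0.427353799294,0.197949332757,0.369752566838,0.0819593185568
max_seasonal_precip,-0.204024761682,0.197584421381,-0.375820655994,0.194923069665,-0.216267548274,0.530788907211,1,0.151249125626,-0.156454116383,-0.0766985388717,0.315711348955,0.275527655412
min_seasonal_precip,-0.111409820033,0.282170276239,0.184298996585,-0.13241350396,0.200536245467,0.312877267721,0.151249125626,1,-0.127622296622,-0.021285516593,0.164922149641,0.126862778837
vpd,0.858763671082,-0.265922003147,-0.160097430008,0.471594752931,0.0974436376031,-0.427353799294,-0.156454116383,-0.127622296622,1,0.12011807918,-0.353020410653,0.122568469904
max_drought_dur,-0.107639288739,-0.249863845844,0.038780175323,0.206035945168,-0.344888070258,0.197949332757,-0.0766985388717,-0.021285516593,0.12011807918,1,-0.0399645821868,-0.183472913872
max_heatwave_dur,-0.502297713001,0.416670716312,-0.210774761618,-0.32872212553,-0.314937217853,0.369752566838,0.315711348955,0.164922149641,-0.353020410653,-0.0399645821868,1,0.344406357281
max_dryspell_dur,0.111949517229,0.0985966180369,-0.105552704654,0.127870208118,0.220607708053,0.0819593185568,0.275527655412,0.126862778837,0.122568469904,-0.183472913872,0.344406357281,1
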