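metric_a,metric_b,r,reason
mean_temp,vpd,0.858763671082,|r| >= 0.6
mean_precip,precip_var,-0.606855012214,|r| >= 0.6
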