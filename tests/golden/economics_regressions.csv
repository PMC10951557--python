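component,moderator,k,slope,se,p,pseudo_r2
PC1,mean_temp,20,0.0848400676504,0.219708820517,0.69938724449,0
PC1,mean_precip,20,-0.000873814481272,0.58090847856,0.998799806086,0
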