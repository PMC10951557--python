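covariate,k,adj_r2,p
growth_form,20,-0.101377902437,0.743171877491
maturity_age,20,0.0991238676562,0.0957387964396
lifespan,20,-0.0549249224018,0.918528859215
d_co2,20,-0.0554669004701,0.969411262469
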