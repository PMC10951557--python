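species,PC1
sp01,-0.067500248679
sp02,0.0172593665694
sp03,0.161556738415
sp04,0.15959235618
sp05,-0.0596203928547
sp06,0.201822665945
sp07,-0.052264621483
sp08,0.203055183023
sp09,-0.283865871098
sp10,-0.198078778216
sp11,-0.213042313049
sp12,0.0485723342088
sp13,0.0960313796574
sp14,0.111707532789
sp15,0.0259473863219
sp16,-0.0794477048073
sp17,0.00797142256767
sp18,-0.0582557344482
sp19,-0.0873284087918
sp20,0.065887707749
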