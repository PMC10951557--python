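species,overall_change
sp01,0.00611926208828
sp02,0.139779289588
sp03,0.121522206875
sp04,0.151998166716
sp05,0.0464292311584
sp06,0.135158789471
sp07,0.0442061099861
sp08,0.167711032105
sp09,0.0887566744721
sp10,0.0763208267677
sp11,0.00455165596643
sp12,0.0669706894789
sp13,0.00830635278575
sp14,0.0773869634601
sp15,0.0713221688301
sp16,0.0289426050058
sp17,0.0216377811146
sp18,0.0583961389782
sp19,0.0557955212911
sp20,0.057439032067
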