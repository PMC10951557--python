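species,trait,u,true_lnrr,observed_lnrr,dropped
sp01,leaf_area,-0.0666376162724,-0.0150118204046,-0.0150118204046,False
sp01,sla,-0.0429821026132,0.00864369325461,0.00864369325461,False
sp01,asat,0.0184117731441,0.0700375690119,0.0700375690119,False
sp01,nitrogen,0.0307877768073,0.0824135726751,0.0824135726751,False
sp02,leaf_area,0.00728009597181,0.0658670449932,0.0658670449932,False
sp02,sla,0.0104831983596,0.069070147381,0.069070147381,False
sp02,asat,-0.0700191963821,-0.0114322473607,-0.0114322473607,False
sp02,nitrogen,0.0216511808252,0.0802381298466,0.0802381298466,False
sp03,leaf_area,0.0105032099841,0.0442873518226,0.0442873518226,False
sp03,sla,0.00908032044353,0.042864462282,0.042864462282,False
sp03,asat,0.0454322298158,0.0792163716542,0.0792163716542,False
sp03,nitrogen,0.00740490572985,0.0411890475683,0.0411890475683,False
sp04,leaf_area,-0.0326770675073,0.0172397017754,0.0172397017754,False
sp04,sla,0.0166443228372,0.0665610921198,0.0665610921198,False
sp04,asat,0.0153517296033,0.0652684988859,0.0652684988859,False
sp04,nitrogen,-0.0191602903569,0.0307564789258,0.0307564789258,False
sp05,leaf_area,0.0440357954117,0.04333557455,0.04333557455,False
sp05,sla,-0.0142026051028,-0.0149028259645,-0.0149028259645,False
sp05,asat,-0.00357315495271,-0.0042733758144,-0.0042733758144,False
sp05,nitrogen,-0.0123256849491,-0.0130259058108,-0.0130259058108,False
sp06,leaf_area,0.00175196000462,0.106993168715,0.106993168715,False
sp06,sla,-0.00693258642507,0.0983086222853,0.0983086222853,False
sp06,asat,0.016907184699,0.122148393409,0.122148393409,False
sp06,nitrogen,0.00462656049023,0.109867769201,0.109867769201,False
sp07,leaf_area,-0.0116607319767,0.0454913102012,0.0454913102012,False
sp07,sla,0.0615906377714,0.118742679949,0.118742679949,False
sp07,asat,0.0264555734728,0.0836076156507,0.0836076156507,False
sp07,nitrogen,-0.063632297355,-0.00648025517713,-0.00648025517713,False
sp08,leaf_area,0.00217029279231,0.0822019205469,0.0822019205469,False
sp08,sla,0.000593260474707,0.0806248882293,0.0806248882293,False
sp08,asat,0.0404657590273,0.120497386782,0.120497386782,False
sp08,nitrogen,0.0309324115055,0.11096403926,0.11096403926,False
sp09,leaf_area,0.0618597529672,0.0837593492558,0.0837593492558,True
sp09,sla,-0.02227645011,-0.000376853821453,-0.000376853821453,False
sp09,asat,0.00226543337521,0.0241650296638,0.0241650296638,False
sp09,nitrogen,-0.0174095827449,0.00449001354368,0.00449001354368,False
sp10,leaf_area,0.010250352441,0.00978387796631,0.00978387796631,False
sp10,sla,-0.0696617832278,-0.0701282577025,-0.0701282577025,False
sp10,asat,-0.0122294899418,-0.0126959644165,-0.0126959644165,False
sp10,nitrogen,-0.0352269733924,-0.0356934478671,-0.0356934478671,False
sp11,leaf_area,0.0342912428806,0.0370224939847,0.0370224939847,False
sp11,sla,0.0406818149062,0.0434130660103,0.0434130660103,False
sp11,asat,-0.00858867145318,-0.00585742034908,-0.00585742034908,False
sp11,nitrogen,-0.0125416620973,-0.00981041099324,-0.00981041099324,False
sp12,leaf_area,-0.0115819048336,0.0184226543879,0.0184226543879,False
sp12,sla,-0.0166476714712,0.0133568877503,0.0133568877503,False
sp12,asat,0.0039041376142,0.0339086968357,0.0339086968357,False
sp12,nitrogen,-0.0186675504887,0.0113370087328,0.0113370087328,False
sp13,leaf_area,-0.00176317646709,0.00377105296535,0.00377105296535,False
sp13,sla,-0.00705646471532,-0.00152223528287,-0.00152223528287,False
sp13,asat,0.024903550126,0.0304377795585,0.0304377795585,False
sp13,nitrogen,-0.0161588383074,-0.0106246088749,-0.0106246088749,True
sp14,leaf_area,0.00819623383822,0.0822865968791,0.0822865968791,False
sp14,sla,0.0398445317944,0.113934894835,0.113934894835,False
sp14,asat,0.00210813406618,0.076198497107,0.076198497107,False
sp14,nitrogen,0.0363114498264,0.110401812867,0.110401812867,False
sp15,leaf_area,-0.0303943412554,0.0667535496031,0.0667535496031,False
sp15,sla,-0.00883241030211,0.0883154805563,0.0883154805563,False
sp15,asat,0.0184247624874,0.115572653346,0.115572653346,False
sp15,nitrogen,-0.0166794245229,0.0804684663356,0.0804684663356,False
sp16,leaf_area,-0.00177439038229,-0.0819763781325,-0.0819763781325,False
sp16,sla,-0.0198348136527,-0.100036801403,-0.100036801403,False
sp16,asat,0.00157052277322,-0.078631464977,-0.078631464977,False
sp16,nitrogen,0.00432728713392,-0.0758747006163,-0.0758747006163,False
sp17,leaf_area,0.046184517641,0.0726724893446,0.0726724893446,False
sp17,sla,0.0419995262692,0.0684874979728,0.0684874979728,False
sp17,asat,-0.000264779873882,0.0262231918297,0.0262231918297,False
sp17,nitrogen,0.0636077750762,0.0900957467798,0.0900957467798,False
sp18,leaf_area,0.0115582280293,0.0370309607407,0.0370309607407,False
sp18,sla,-0.0256519154991,-0.000179182787784,-0.000179182787784,False
sp18,asat,-0.00964777293755,0.0158249597738,0.0158249597738,False
sp18,nitrogen,-0.0715677486535,-0.0460950159422,-0.0460950159422,False
sp19,leaf_area,0.0114059419192,-0.0109060341064,-0.0109060341064,False
sp19,sla,-0.0215648547047,-0.0438768307303,-0.0438768307303,False
sp19,asat,0.0545059287718,0.0321939527462,0.0321939527462,False
sp19,nitrogen,0.0222050785527,-0.000106897472881,-0.000106897472881,False
sp20,leaf_area,-0.02843169987,0.069201335793,0.069201335793,False
sp20,sla,-0.0422188535738,0.0554141820892,0.0554141820892,False
sp20,asat,-0.0145957422712,0.0830372933918,0.0830372933918,False
sp20,nitrogen,0.0141578269402,0.111790862603,0.111790862603,True
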