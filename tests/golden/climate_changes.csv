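species,mean_temp,mean_precip,temp_var,precip_var,temp_range,precip_range,max_seasonal_precip,min_seasonal_precip,vpd,max_drought_dur,max_heatwave_dur,max_dryspell_dur
sp01,1.7054603906,0.163889954292,0.00790113963136,0.217152914718,2.45565745589,0.342422291548,0.129326384218,0.136491882407,0.172479136986,0.555946059046,-0.336472236621,0
sp02,0.770397589504,-0.164082640652,0.00165031440924,0.00228587086381,0.948652920001,0.180115335518,-0.00171878075434,-0.775637299125,0.0771220932751,0.154150679827,0.200670695462,0
sp03,2.45028922677,0.343662344355,0.0174131896658,-0.0736679154782,4.07072503194,-0.214860984134,-0.218611241103,0.238394418288,0.127081274901,0.0896121586897,-0.887303195001,-0.485507815782
sp04,1.33244355498,0.517375989274,0.0358449468153,-0.195846149739,3.50080278734,-0.37483865834,0.0675232095983,-0.551298863328,0.0664286953231,-0.667829372576,-0.167054084663,0.485507815782
sp05,-0.82493463345,0.421016277367,-0.025453545214,-0.0484486668488,1.81148111743,0.354981466993,0.107111706012,0.0419747732197,-0.0509921334771,-0.236388778064,0.405465108108,0.287682072452
sp06,2.10482417421,0.233079726205,0.0355911341699,-0.287286005621,5.98875758643,-0.478674758489,-0.100629856752,0.0437551461135,0.0894583108819,-0.39304258811,0,-0.200670695462
sp07,1.29125678787,-0.0454062137482,0.0196122554789,0.125229631314,2.81934643464,-0.094858348243,0.000175229602468,-0.285360992463,0.155456133899,0.470003629246,-0.0741079721537,0
sp08,2.71986413096,-0.682814956794,-0.0342059476841,0.244225787219,2.30739724317,-0.125041907066,0.0988615620288,-0.298200275118,0.164758998962,-0.157628944204,-0.559615787935,0
sp09,0.202425854459,0.0657644220752,-0.0114228270967,0.149602723188,-1.16820084944,0.0128837695861,0.0961680724656,-0.244783745196,0.0461803971288,0.287682072452,0.117783035656,0.143100843641
sp10,0.472994624139,0.45154750857,-0.0269659424753,-0.114260101773,-0.613608197418,0.106958339675,0.0914624488449,-0.938309392744,-0.0278438609379,-0.30010459245,-0.241162056817,-0.69314718056
sp11,-0.231576665199,0.127416652509,0.00306966817489,-0.156965768283,0.106862203632,0.245209342298,0.211434800634,0.87184687508,-0.0468403528905,0.19782574333,0.143100843641,-0.287682072452
sp12,0.760176599776,-0.201787516249,-0.0450405606323,0.100174912888,-1.00015828512,-0.102960990936,0.132396651652,-0.25492089427,0.112992170382,0.0317486983146,-0.0800427076735,-0.318453731119
sp13,0.783629061891,-0.366893424593,0.0432165243597,-0.0390622061546,-0.807610570783,-0.330282125496,-0.107924449896,0.0579495570997,0.0828449478769,0.0984400728133,-0.336472236621,-0.938269638593
sp14,1.14769909149,0.415184851795,-0.0131605063094,-0.250184267278,-0.187090146965,-0.177538421289,-0.203151952595,-0.133944040026,0.0577650289367,0.341749293722,0.167054084663,-0.0870113769896
sp15,2.4252819308,-0.217668188913,-0.0410259234041,0.324795141869,1.30994835114,-0.146518069804,0.0127883300429,-0.463291711584,0.2247908271,-0.312374685042,-0.241162056817,-0.223143551314
sp16,-1.13126219888,0.0499977232951,0.0279246800624,0.0689583244092,4.42729102651,0.45958881973,0.128239104339,0.316194259254,-0.081974265207,-0.139761942375,-0.236388778064,-0.435318071258
sp17,1.05448796301,-0.0559456112709,0.011768042419,0.102682577747,3.27340646813,-0.0901760187905,-0.293756768827,0.151195641942,0.0649986167717,-0.31508104664,-0.262364264467,-0.485507815782
sp18,1.56164084602,-0.731557506164,0.00910957647034,0.224614827912,3.05451551136,-0.257066166647,0.0410076557679,-0.41872086498,0.0562585722681,0.032789822823,-0.526093095897,0.441832752279
sp19,0.22670495273,-0.683694546156,0.0231052610284,0.0367373091328,2.14055038699,-0.189796421638,-0.375038858667,-0.446106012859,0.0516076235983,0.158224005215,-0.336472236621,0
sp20,1.56434868438,0.443249474085,-0.00737960555295,0.0305724386536,2.39596217483,0.163878027391,0.120768414327,1.10465276587,0.115874043797,-0.494696241836,0.194156014441,0.864997437487
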