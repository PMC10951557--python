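species,trait,yi,vi,flag
sp01,asat,-0.0751964943287,0.0106766380732,
sp01,leaf_area,0.0307276765625,0.0123997858369,
sp01,nitrogen,0.135937803659,0.00630940201064,
sp01,sla,-0.0669919375393,0.00635680415954,
sp02,asat,-0.00208638914349,0.011753379685,
sp02,leaf_area,0.313610193438,0.0130391451364,
sp02,nitrogen,0.114116079017,0.00765860006671,
sp02,sla,0.133477275038,0.00831702276475,
sp03,asat,0.228105937148,0.00814239972888,
sp03,leaf_area,0.193149066091,0.00770533260493,
sp03,nitrogen,0.141083386385,0.0096824240117,
sp03,sla,-0.0762495621247,0.012542599121,
sp04,asat,0.20669419559,0.00508538547164,
sp04,leaf_area,0.14172256303,0.00795439997602,
sp04,nitrogen,0.072051655287,0.00716268657395,
sp04,sla,0.187524252956,0.00449749265818,
sp05,asat,0.049418649678,0.00479967712882,
sp05,leaf_area,-0.165273291276,0.00657564825178,
sp05,nitrogen,-0.000901064244993,0.0061027544329,
sp05,sla,-0.0689612187909,0.0118451656619,
sp06,asat,0.16162710318,0.00521977892956,
sp06,leaf_area,0.0248103172018,0.00719835052031,
sp06,nitrogen,0.208705592935,0.0101692663867,
sp06,sla,0.145492144567,0.00746257671886,
sp07,asat,-0.0497893487841,0.00661986118146,
sp07,leaf_area,0.0248185977316,0.00704225630346,
sp07,nitrogen,0.0556930321741,0.00654518380372,
sp07,sla,0.146102158823,0.00529324846169,
sp08,asat,0.14896169438,0.00958505159092,
sp08,leaf_area,0.172457909913,0.00936726166918,
sp08,nitrogen,0.237671577034,0.00426461509437,
sp08,sla,0.111752947091,0.0079455493905,
sp09,asat,-0.240138293878,0.00709393519377,
sp09,nitrogen,-0.0407118527288,0.00287716950292,
sp09,sla,0.0145801231906,0.00751064719561,
sp10,asat,-0.0093464131593,0.00369466530476,
sp10,leaf_area,-0.0509385551915,0.00603035188175,
sp10,nitrogen,-0.139466734017,0.0108309467884,
sp10,sla,-0.105531604703,0.00591952929719,
sp11,asat,-0.17268493009,0.0133701204817,
sp11,leaf_area,0.0931693638042,0.00779392705016,
sp11,nitrogen,-0.0377576029198,0.0110516251311,
sp11,sla,0.0990665453394,0.00886447731276,
sp12,asat,-0.0352924560793,0.0073076627589,
sp12,leaf_area,0.0145999348033,0.00728493468093,
sp12,nitrogen,0.230598747092,0.0110188124924,
sp12,sla,0.0579765321001,0.00599007983067,
sp13,asat,0.0937521358906,0.0039447867336,
sp13,leaf_area,-0.193375780652,0.00745050054879,
sp13,sla,0.124542703119,0.0191700876528,
sp14,asat,0.0930379118682,0.00214018448702,
sp14,leaf_area,0.00957902492171,0.00762707557261,
sp14,nitrogen,0.192292266245,0.00963128631794,
sp14,sla,0.0146386508056,0.0100589415702,
sp15,asat,0.138177704244,0.00647854009313,
sp15,leaf_area,0.0806672297383,0.00895426644025,
sp15,nitrogen,-0.0270817267093,0.00669603423159,
sp15,sla,0.0935254680474,0.00699583510831,
sp16,asat,-0.0332514449285,0.0100461595485,
sp16,leaf_area,-0.0994903028548,0.0118432658438,
sp16,nitrogen,0.0567819543153,0.00775630784835,
sp16,sla,-0.0398106265552,0.0061177691472,
sp17,asat,0.0517098645933,0.00540376346956,
sp17,leaf_area,-0.047403582279,0.00373450607036,
sp17,nitrogen,0.0800100770232,0.0080164928374,
sp17,sla,0.00223476512078,0.00595422455681,
sp18,asat,-0.0138878318898,0.00642708037087,
sp18,leaf_area,0.0568721194559,0.00705862076773,
sp18,nitrogen,-0.0193819279431,0.0149299336196,
sp18,sla,0.20998219629,0.00766409986897,
sp19,asat,0.0754728456447,0.00524411153314,
sp19,leaf_area,0.188412551946,0.00812134866106,
sp19,nitrogen,-0.132679091468,0.0111992965153,
sp19,sla,0.0919757790421,0.00787723261993,
sp20,asat,0.0752075766748,0.00654749056583,
sp20,leaf_area,-0.00668433860784,0.0084167213358,
sp20,sla,0.103793858134,0.00727697363059,
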