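study_id,ethnicity,complications,case_cc,case_ct,case_tt,ctrl_cc,ctrl_ct,ctrl_tt,reported_hwe_p
Bazzaz 2010,Asian,present_or_unreported,148,102,31,113,80,14,1.000
Chang 2011,Asian,present_or_unreported,1,25,30,3,23,36,1.000
Chauhan 2012,Asian,present_or_unreported,31,310,677,45,335,626,1.000
Chen 2010,Asian,explicitly_absent,23,13,4,34,17,4,0.439
Dai 2012,Asian,explicitly_absent,29,28,3,31,27,2,0.310
Eroglu 2007,Asian,explicitly_absent,25,25,6,63,58,7,0.272
Hasegawa 2003,Asian,present_or_unreported,23,32,7,78,96,26,0.762
Ho 2005,Asian,explicitly_absent,13,5,2,28,11,3,0.326
Luo 2009,Asian,explicitly_absent,39,26,6,43,31,11,0.204
Mao 2004,Asian,explicitly_absent,19,17,5,26,18,3,1.000
Mei 2012,Asian,present_or_unreported,19,70,27,14,73,37,0.025
Movva 2011,Asian,explicitly_absent,68,32,0,91,9,0,1.000
Raza 2012,Asian,present_or_unreported,35,37,15,49,26,13,0.009
Shi 2006,Asian,explicitly_absent,70,29,5,68,34,8,0.273
Sun 2006,Asian,explicitly_absent,60,27,17,63,31,20,<0.001
Tutuncu 2005,Asian,present_or_unreported,39,37,11,47,39,5,0.593
Xiao 2006,Asian,explicitly_absent,8,31,2,47,25,1,0.439
Xu 2003,Asian,explicitly_absent,24,21,9,20,25,7,1.000
Wang 2001,Asian,explicitly_absent,57,48,12,37,38,10,1.000
Wen 2008,Asian,explicitly_absent,21,32,6,27,25,5,1.000
Yang 2001,Asian,explicitly_absent,32,56,14,26,28,8,1.000
Yilmaz 2004,Asian,present_or_unreported,121,98,30,101,93,20,1.000
Yue 2006,Asian,explicitly_absent,43,76,21,17,11,2,1.000
Zhang 2002,Asian,explicitly_absent,32,55,13,40,49,11,0.662
Zhang 2010,Asian,present_or_unreported,73,98,35,53,103,38,0.388
Zhou 2004,Asian,explicitly_absent,5,42,20,8,31,30,1.000
Benes 2001,Caucasian,explicitly_absent,24,20,5,86,106,17,0.062
Bluthner 1999,Caucasian,explicitly_absent,63,65,18,67,68,15,0.853
Cenerelli 2002,Caucasian,explicitly_absent,8,14,8,13,21,9,1.000
Helfenstein 2005,Caucasian,explicitly_absent,26,20,4,26,24,6,1.000
Ksiazek 2004,Caucasian,present_or_unreported,82,58,15,71,83,16,0.304
Mazza 2005,Caucasian,explicitly_absent,35,47,23,35,66,19,0.264
Russo 2008,Caucasian,explicitly_absent,28,42,20,23,50,18,0.403
Soares 2008,Caucasian,explicitly_absent,5,2,0,9,5,2,0.530
Wirta 2002,Caucasian,present_or_unreported,44,29,8,60,47,7,0.811
Benrahma 2012,African,present_or_unreported,160,97,25,114,122,26,0.487
Mackawy 2011,African,explicitly_absent,24,10,6,32,6,2,0.090
Mehri 2010,African,present_or_unreported,50,49,16,66,38,12,0.095
Mtiraoui 2007,African,present_or_unreported,152,79,36,270,94,36,<0.001
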