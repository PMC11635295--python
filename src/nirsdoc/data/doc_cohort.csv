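no,diagnosis,age,gender,crsr,duration_days,etiology,site_of_injury
1,MCS,69,M,9(132102),99,TBI,Supratentorial cerebral cortex
2,MCS,69,M,10(232102),154,TBI,Supratentorial cerebral cortex
3,MCS,61,M,9(132102),315,TBI,Supratentorial cerebral cortex
4,MCS,19,M,9(132102),182,VE,Cerebral cortex
5,MCS,51,M,10(232102),104,Stroke,Right side supratentorial thalamus
6,MCS,8,M,15(244203),162,HIE,Supratentorial thalamus
7,MCS,67,F,10(133102),78,TBI,Supratentorial cerebral cortex
8,MCS,67,F,12(333102),113,TBI,Supratentorial cerebral cortex
9,UWS,62,M,5(002102),52,Stroke,Supratentorial cerebral cortex
10,UWS,31,M,7(112102),133,TBI,Supratentorial thalamus
11,UWS,52,F,8(122102),152,Stroke,Supratentorial cerebral cortex
12,UWS,69,M,8(122102),422,Stroke,Right side supratentorial thalamus
13,UWS,50,F,7(112102),451,Stroke,Left side supratentorial thalamus
14,UWS,61,M,8(122102),314,TBI,Supratentorial cerebral cortex
15,UWS,72,F,5(112100),95,HIE,Cerebral cortex
16,UWS,55,M,7(112102),198,HIE,Cerebral cortex
17,UWS,50,F,8(122102),66,TBI,Supratentorial cerebral cortex
18,UWS,65,F,7(112102),314,Stroke,Supratentorial thalamus
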