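month,DED,SO2,PM2.5,PM10,NO2,CO,O3,AP,AT,RH,PR,WS,AV
1,9.2,45,80,103,45,1.14,51,1014,-13,63,125,2.40,20.28
2,5.3,32,54,76,34,0.92,72,1010,-8,53,121,2.74,19.64
3,11.4,22,68,106,41,0.94,95,1006,3,46,136,2.93,17.57
4,9.7,10,35,87,31,0.68,104,999,11,43,199,3.32,19.82
5,7.4,7,24,67,29,0.61,113,990,18,52,317,3.34,18.01
6,7.6,6,22,46,34,0.66,117,989,22,66,326,2.46,17.06
7,7.8,5,20,41,27,0.65,104,990,24,77,226,2.36,18.75
8,10.4,5,16,35,26,0.66,75,991,21,81,407,2.20,13.46
9,7.1,7,21,47,32,0.70,70,997,16,69,270,2.33,16.24
10,9.2,13,43,72,39,0.88,59,1004,5,62,125,2.54,16.33
11,8.3,23,46,68,36,0.85,45,1006,-5,59,134,2.93,20.43
12,6.5,32,59,76,38,1.01,48,1008,-10,65,119,2.56,22.45
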