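month,DED,SO2,PM2.5,PM10,NO2,CO,O3,AP,AT,RH,PR,WS,AV
1,1.9,18,22,17,5,0.2,5,15,2,9,66,0.3,NA
2,3.4,14,16,13,5,0.2,8,16,5,6,95,0.2,NA
3,1.8,9,20,15,3,0.2,8,16,3,6,94,0.4,NA
4,1.5,4,8,17,4,0.2,3,15,3,9,145,0.2,NA
5,0.7,2,3,18,2,0.1,7,14,2,6,128,0.3,NA
6,1.1,2,3,4,4,0.1,3,14,1,2,151,0.1,NA
7,1.7,2,4,5,3,0.1,16,13,2,4,137,0.1,NA
8,2.6,2,4,7,3,0.1,12,13,2,4,172,0.2,NA
9,0.8,2,5,6,2,0.1,8,13,3,6,93,0.3,NA
10,2.7,4,14,18,3,0.2,9,15,4,8,68,0.0,NA
11,0.9,10,16,15,3,0.2,2,14,4,6,81,0.3,NA
12,1.6,16,16,18,9,0.3,14,15,2,8,64,0.2,NA
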