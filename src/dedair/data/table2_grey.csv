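row,SO2,PM2.5,PM10,NO2,CO,O3,AP,AT,RH,PR,WS,AV
1,0.61,0.70,0.81,0.86,0.83,0.79,0.89,0.36,0.89,0.79,0.88,0.87
2,0.60,0.70,0.80,0.83,0.78,0.84,0.80,0.47,0.79,0.80,0.80,0.76
3,0.80,0.89,0.92,0.84,0.80,0.89,0.83,0.61,0.75,0.73,0.88,0.81
4,0.76,0.83,0.84,0.91,0.86,0.89,0.89,0.85,0.77,0.80,0.90,0.85
5,0.78,0.86,0.91,0.96,0.90,0.77,0.94,0.53,0.93,0.66,0.82,0.92
6,0.76,0.82,0.87,0.91,0.88,0.75,0.92,0.44,0.90,0.79,0.95,0.87
7,0.73,0.81,0.84,0.89,0.85,0.81,0.90,0.39,0.86,0.80,0.91,0.76
8,0.65,0.67,0.70,0.79,0.81,0.84,0.88,0.48,0.87,0.69,0.80,0.71
9,0.77,0.81,0.88,0.95,0.96,0.98,0.93,0.52,0.84,0.74,0.92,0.90
10,0.81,0.91,0.95,0.92,0.91,0.86,0.89,0.81,0.87,0.79,0.88,0.86
11,0.83,0.88,0.94,0.94,0.94,0.80,0.96,0.54,0.94,0.88,0.95,0.92
12,0.67,0.74,0.82,0.81,0.81,0.87,0.87,0.42,0.83,0.77,0.88,0.79
grade,0.73,0.80,0.86,0.89,0.86,0.84,0.89,0.53,0.85,0.77,0.88,0.83
rank,11,9,5,2,4,7,1,12,6,10,3,8
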