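mouse,week,TTV,AVT,SDV
M1,w13,0.560,0.112,0.043
M1,w18,4.848,0.269,0.160
M2,w13,0.960,0.192,0.044
M2,w18,5.608,0.312,0.232
M3,w13,0.560,0.140,0.040
M3,w18,7.336,0.524,0.371
M4,w13,0.616,0.123,0.065
M4,w18,2.624,0.262,0.170
M5,w13,1.184,0.197,0.102
M5,w18,4.784,0.532,0.449
M6,w13,1.328,0.190,0.179
M6,w18,4.816,0.401,0.493
M7,w13,2.232,0.319,0.232
M7,w18,5.328,0.484,0.503
M8,w13,2.048,0.341,0.271
M8,w18,6.120,0.612,0.935
M9,w13,1.600,0.267,0.149
M9,w18,6.808,0.454,0.335
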