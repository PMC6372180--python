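mouse,tumour,volume_w13_mm3,volume_w18_mm3
M1,T1,0.080,0.304
M1,T2,0.072,0.288
M1,T3,0.160,0.416
M1,T4,0.168,0.752
M1,T5,0.080,0.336
M1,T6,-,0.200
M1,T7,-,0.096
M1,T8,-,0.152
M1,T9,-,0.240
M1,T10,-,0.480
M1,T11,-,0.112
M1,T12,-,0.104
M1,T13,-,0.184
M1,T14,-,0.128
M1,T15,-,0.304
M1,T16,-,0.304
M1,T17,-,0.320
M1,T18,-,0.128
M2,T1,0.136,0.272
M2,T2,0.176,0.248
M2,T3,0.184,1.184
M2,T4,0.272,0.392
M2,T5,0.192,0.288
M2,T6,-,0.120
M2,T7,-,0.192
M2,T8,-,0.152
M2,T9,-,0.328
M2,T10,-,0.256
M2,T11,-,0.232
M2,T12,-,0.352
M2,T13,-,0.304
M2,T14,-,0.104
M2,T15,-,0.200
M2,T16,-,0.472
M2,T17,-,0.360
M2,T18,-,0.152
M3,T1,0.168,1.072
M3,T2,0.080,1.496
M3,T3,0.184,0.528
M3,T4,0.128,0.288
M3,T5,-,0.368
M3,T6,-,0.592
M3,T7,-,0.760
M3,T8,-,0.480
M3,T9,-,0.360
M3,T10,-,0.416
M3,T11,-,0.088
M3,T12,-,0.208
M3,T13,-,0.608
M3,T14,-,0.072
M4,T1,0.192,0.488
M4,T2,0.104,0.176
M4,T3,0.056,0.176
M4,T4,0.056,0.120
M4,T5,-,0.152
M4,T6,-,0.152
M4,T7,-,0.184
M4,T8,-,0.200
M4,T9,-,0.304
M4,T10,0.208,0.672
M5,T1,0.288,0.680
M5,T2,0.152,0.296
M5,T3,0.160,0.408
M5,T4,0.056,0.176
M5,T5,0.368,1.416
M5,T6,-,0.344
M5,T7,-,1.200
M5,T8,0.160,0.208
M5,T9,-,0.056
M6,T1,0.184,0.672
M6,T2,0.144,0.248
M6,T3,0.056,0.248
M6,T4,0.616,1.952
M6,T5,0.144,0.256
M6,T6,0.056,0.440
M6,T7,0.128,0.248
M6,T8,-,0.072
M6,T9,-,0.256
M6,T10,-,0.248
M6,T11,-,0.072
M6,T12,-,0.104
M7,T1,0.840,1.904
M7,T2,-,0.136
M7,T3,0.200,0.472
M7,T4,0.232,0.608
M7,T5,0.144,0.328
M7,T6,0.320,0.552
M7,T7,0.392,0.792
M7,T8,-,0.056
M7,T9,-,0.176
M7,T10,-,0.072
M7,T11,0.104,0.232
M8,T1,0.936,3.368
M8,T2,0.176,0.528
M8,T3,0.336,0.592
M8,T4,0.224,0.304
M8,T5,0.192,0.488
M8,T6,-,0.072
M8,T7,0.184,0.328
M8,T8,-,0.096
M8,T9,-,0.192
M8,T10,-,0.152
M9,T1,0.496,1.152
M9,T2,0.104,1.136
M9,T3,0.288,0.320
M9,T4,0.072,0.712
M9,T5,-,0.296
M9,T6,0.392,0.544
M9,T7,-,0.520
M9,T8,-,0.264
M9,T9,-,0.376
M9,T10,-,0.144
M9,T11,-,0.080
M9,T12,0.248,0.712
M9,T13,-,0.344
M9,T14,-,0.056
M9,T15,-,0.152
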