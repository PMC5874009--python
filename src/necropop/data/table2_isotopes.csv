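individual_id,material,tooth,ratio,two_se
MV 1,enamel,LM1-lower,0.708856,0.000005
MV 2,enamel,RM2-upper,0.708974,0.000006
MV 2,enamel,RM3-lower,0.709032,0.000006
MV 3,enamel,LM1-lower,0.708977,0.000007
MV 3,enamel,RM3-upper,0.708779,0.000007
MV 5,enamel,LM3-lower,0.709108,0.000006
MV 7,enamel,LM1-lower,0.708896,0.000007
MV 7,enamel,LM2-upper,0.709337,0.000006
MV 8,bone,,0.708733,0.000006
MV 8,enamel,LM1-upper,0.708914,0.000007
MV 8,enamel,RM3-lower,0.708838,0.000005
MV 10,enamel,Ldm2-lower,0.708793,0.000006
MV 10,enamel,RM1-lower,0.708866,0.000006
MV 12,enamel,RM1-upper,0.709257,0.000007
MV 12,enamel,RM2-lower,0.708980,0.000005
MV 15,enamel,LM1-lower,0.709266,0.000005
MV 15,enamel,RM3-lower,0.709319,0.000007
MV 19,enamel,LM1-lower,0.709070,0.000006
MV 19,enamel,LM3-lower,0.709192,0.000006
MV 20,enamel,LM1-lower,0.709478,0.000008
MV 20,enamel,LM2-lower,0.709482,0.000005
MV 21,enamel,LP4-upper,0.708501,0.000008
MV 21,enamel,RM1-lower,0.708533,0.000007
MV 22,bone,,0.708685,0.000007
MV 22,enamel,LP4-lower,0.709043,0.000006
MV 22,enamel,RM1-lower,0.709032,0.000006
MV 24,enamel,Rdm2-lower,0.708757,0.000007
MV 24,enamel,RM1-lower,0.708814,0.000006
MV 25,enamel,Rdm2-lower,0.708755,0.000005
MV 25,enamel,RM1-lower,0.708810,0.000005
MV 26,bone,,0.708701,0.000007
MV 26,enamel,LM1-lower,0.709143,0.000006
MV 26,enamel,LM2-lower,0.708997,0.000004
MV 27,bone,,0.708691,0.000007
MV 27,enamel,RM1-upper,0.709354,0.000008
MV 27,enamel,RM3-upper,0.708812,0.000005
MV 30,enamel,LM1-upper,0.708944,0.000007
MV 30,enamel,RM3-upper,0.708743,0.000005
MV 31,bone,,0.708826,0.000007
MV 31,enamel,LM1-lower,0.709363,0.000007
MV 31,enamel,LM3-lower,0.709289,0.000004
MV 35,enamel,Ldm2-upper,0.708806,0.000006
MV 35,enamel,LM1-lower,0.708740,0.000005
MV 39,enamel,LM1-upper,0.708763,0.000005
MV 39,enamel,RM3-lower,0.708749,0.000005
MV A,enamel,LM3-upper,0.708850,0.000006
MV A,enamel,RM1-upper,0.709101,0.000004
MV B,enamel,LM1-upper,0.708879,0.000006
MV B,enamel,LM2-lower,0.708947,0.000005
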