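dataset,Operability,Completeness,Correctness,Timeliness,total
Elderly,0.251,0.250,0.260,0.174,0.935
LLOS,0.251,0.227,0.264,0.224,0.966
Stroke,0.251,0.250,0.263,0.177,0.941
ARF,0.251,0.230,0.263,0.163,0.907
CIR,0.251,0.231,0.264,0.183,0.929
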