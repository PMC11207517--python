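treatment,stage,comprehensive
T6,GM,0.120
T6,V1,0.458
T6,RR,0.953
T7,GM,0.028
T7,V1,0.531
T7,RR,0.799
T8,GM,0.065
T8,V1,0.145
T8,V2,0.346
T8,V3,0.831
T8,RR,0.920
T9,GM,0.098
T9,V1,0.275
T9,V2,0.409
T9,V3,0.720
T9,RR,0.870
T10,GM,0.151
T10,V1,0.254
T10,V2,0.546
T10,V3,0.733
T10,RR,0.852
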