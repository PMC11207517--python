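criterion,r
ci,0.709
ssc,0.869
oac,-0.897
ssc_oac,0.917
lycopene,0.774
vc,0.869
firmness,-0.823
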