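factor,criterion,factor_weight,sub_weight,combined_weight
appearance,ci,0.158,0.457,0.072
appearance,firmness,0.158,0.543,0.086
taste,ssc,0.680,0.320,0.218
taste,oac,0.680,0.519,0.353
taste,ssc_oac,0.680,0.161,0.109
nutrition,lycopene,0.162,0.426,0.069
nutrition,vc,0.162,0.574,0.093
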