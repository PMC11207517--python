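factor,criterion,factor_weight,sub_weight,combined_weight
appearance,ci,0.158,0.628,0.099
appearance,firmness,0.158,0.372,0.059
taste,ssc,0.680,0.335,0.228
taste,oac,0.680,0.374,0.254
taste,ssc_oac,0.680,0.290,0.197
nutrition,lycopene,0.162,0.567,0.092
nutrition,vc,0.162,0.432,0.070
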