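treatment,stage,l_star,l_star_sd,a_star,a_star_sd,b_star,b_star_sd,ci,ci_sd,ssc_g100g,ssc_sd,oac_g100g,oac_sd,ssc_oac,vc_mg100g,vc_sd,lycopene_mgkg,lycopene_sd,firmness_kgcm2,firmness_sd,comprehensive
T1,RR,42.10,2.00,14.95,2.61,13.69,2.07,35.03,2.94,3.26,0.23,0.52,0.10,6.32,29.70,1.21,21.57,1.94,5.98,1.51,0.865
T2,RR,41.13,3.83,11.06,1.33,12.05,3.61,32.87,8.66,3.19,0.13,0.51,0.02,6.31,29.15,0.90,19.97,1.13,6.57,1.05,0.843
T3,RR,41.68,1.42,16.27,2.15,13.37,1.85,37.08,3.91,3.07,0.12,0.60,0.02,5.12,26.75,0.53,19.60,0.27,7.98,0.70,0.422
T4,RR,39.24,2.05,14.21,1.73,11.28,2.12,39.93,3.83,3.10,0.05,0.60,0.04,5.18,23.25,1.91,15.22,0.29,9.60,2.30,0.391
T5,RR,41.67,1.29,14.91,3.58,13.57,2.56,35.50,7.86,3.00,0.04,0.71,0.04,4.22,22.95,1.91,13.45,2.15,9.52,1.01,0.016
T6,RR,41.30,2.08,16.74,2.06,13.99,2.63,37.16,4.85,3.17,0.16,0.50,0.03,6.34,32.90,0.76,22.72,0.65,6.77,1.04,0.895
T7,RR,40.69,1.64,17.67,1.93,14.27,1.39,38.24,2.66,3.10,0.25,0.59,0.02,5.25,31.20,4.07,22.37,0.38,8.03,1.51,0.517
T8,RR,40.72,1.62,17.75,2.64,15.16,2.63,37.34,2.83,3.09,0.04,0.52,0.01,5.94,32.60,1.13,22.33,1.81,6.61,0.33,0.830
T9,RR,39.58,1.19,15.38,2.46,12.91,1.12,38.71,3.01,3.00,0.22,0.53,0.02,5.66,32.25,0.57,20.08,1.17,7.35,0.36,0.749
T10,RR,38.99,1.15,17.90,1.21,13.52,1.29,40.93,1.63,3.15,0.06,0.54,0.03,5.82,31.60,1.62,17.79,0.90,8.33,1.23,0.666
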