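treatment,stage,tep_mj_m2,l_star,l_star_sd,a_star,a_star_sd,b_star,b_star_sd,ci,ci_sd,ssc_g100g,ssc_sd,oac_g100g,oac_sd,ssc_oac,vc_mg100g,vc_sd,lycopene_mgkg,lycopene_sd,firmness_kgcm2,firmness_sd
T6,GM,249.70,47.02,1.84,-6.54,0.62,22.51,1.69,-11.94,1.75,2.60,0.12,0.69,0.05,3.76,16.15,0.53,4.40,0.22,13.53,1.50
T6,V1,267.65,45.10,3.58,7.30,5.05,19.23,2.37,15.23,1.80,2.86,0.18,0.64,0.03,4.49,26.25,0.30,9.90,2.91,10.18,1.12
T6,RR,283.39,41.30,2.08,16.74,2.06,13.99,2.63,37.16,1.39,3.17,0.16,0.50,0.03,6.34,32.90,0.76,22.72,0.65,6.77,1.04
T7,GM,232.49,48.83,1.81,-6.95,0.95,23.30,1.79,-11.77,0.92,2.57,0.24,0.80,0.01,3.21,16.95,0.50,4.18,0.22,15.39,0.92
T7,V1,247.68,44.38,3.53,12.14,3.30,16.34,2.94,27.27,1.62,2.80,0.03,0.67,0.04,4.20,24.00,1.23,11.44,0.90,11.57,0.90
T7,RR,263.97,40.69,1.64,17.67,1.93,14.27,1.39,38.24,9.84,3.10,0.25,0.59,0.02,5.25,31.20,4.07,22.37,0.38,8.03,1.51
T8,GM,248.64,48.19,1.20,-6.64,0.43,23.19,2.15,-11.51,8.48,2.59,0.12,0.78,0.03,3.32,16.85,0.53,6.75,0.46,15.03,0.27
T8,V1,258.81,50.07,2.22,-6.98,0.87,23.73,1.96,-11.29,1.11,2.69,0.12,0.70,0.02,3.85,20.85,3.92,6.93,0.58,13.68,0.49
T8,V2,269.87,47.36,1.98,-2.29,1.14,24.53,3.41,-3.89,2.80,2.79,0.16,0.60,0.03,4.65,25.90,0.77,10.90,0.56,8.76,1.14
T8,V3,280.41,42.19,1.12,17.73,2.12,14.74,1.61,36.34,2.05,3.05,0.09,0.56,0.02,5.44,31.65,0.25,21.89,3.80,7.45,0.98
T8,RR,290.10,40.72,1.62,17.75,2.64,15.16,2.63,37.34,1.78,3.09,0.04,0.52,0.01,5.94,32.60,1.13,22.32,1.81,6.60,0.33
T9,GM,245.40,46.69,1.06,-6.49,0.58,20.65,2.39,-12.91,3.38,2.61,0.10,0.73,0.13,3.56,15.30,1.64,7.32,0.13,14.99,0.53
T9,V1,260.16,46.48,2.62,-6.41,1.12,20.73,2.81,-12.93,4.04,2.81,0.20,0.59,0.03,4.72,20.05,0.62,7.23,0.11,13.53,0.59
T9,V2,266.53,47.90,1.29,-0.09,2.03,23.26,3.22,-0.40,3.54,2.84,0.22,0.55,0.01,5.16,28.30,2.61,8.96,0.81,13.10,0.59
T9,V3,271.29,44.65,1.71,11.77,2.84,14.51,1.80,27.87,4.60,2.85,0.11,0.54,0.01,5.30,31.65,0.82,16.37,0.26,8.78,1.08
T9,RR,276.58,39.58,1.19,15.38,2.46,12.91,1.12,38.71,3.35,3.00,0.22,0.53,0.02,5.66,32.25,0.57,20.08,1.17,7.35,0.36
T10,GM,260.16,45.58,1.85,-6.63,0.64,20.35,2.24,-13.69,4.85,2.85,0.26,0.71,0.02,4.01,17.35,0.90,6.84,0.53,14.64,0.77
T10,V1,266.53,47.58,3.26,-5.17,1.09,21.64,2.44,-9.84,2.66,2.93,0.14,0.65,0.01,4.51,26.10,0.82,7.93,0.52,13.57,1.05
T10,V2,271.29,43.78,2.23,7.84,1.98,15.38,1.64,20.49,2.83,2.95,0.18,0.60,0.03,4.93,28.15,1.62,10.26,0.32,12.46,1.47
T10,V3,276.58,42.86,1.95,16.58,1.76,14.27,1.95,35.42,3.01,3.06,0.34,0.57,0.03,5.39,31.60,1.40,13.78,0.58,9.82,2.83
T10,RR,278.11,38.99,1.15,17.90,1.21,13.52,1.29,40.93,1.63,3.15,0.06,0.54,0.03,5.82,31.60,1.62,17.79,0.90,8.33,1.23
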