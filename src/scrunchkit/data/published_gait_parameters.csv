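species,stimulus,concentration,frequency_mean,frequency_sd,max_elongation_mean,max_elongation_sd,speed_mean,speed_sd,asymmetry_mean,asymmetry_sd,gait,n,is_reference
D_japonica,AITC,50 uM,0.72,0.08,0.52,0.04,0.37,0.04,0.59,0.03,S,9,0
D_japonica,H2O2,40 mM,0.54,0.09,0.44,0.04,0.23,0.05,0.60,0.02,S,8,0
D_japonica,capsaicin,165 uM,0.80,0.14,0.48,0.07,0.38,0.05,0.59,0.04,S,8,0
D_japonica,anandamide,100 uM,0.63,0.08,0.43,0.05,0.27,0.05,0.57,0.03,S,8,0
D_japonica,amputation,,0.70,0.27,0.50,0.08,0.34,0.12,0.60,0.12,S,15,1
S_mediterranea,AITC,50 uM,0.33,0.02,0.43,0.05,0.14,0.02,0.58,0.02,S,5,0
S_mediterranea,H2O2,40 mM,0.37,0.03,0.39,0.05,0.14,0.02,0.52,0.02,S,10,0
S_mediterranea,capsaicin,165 uM,0.44,0.04,0.49,0.06,0.21,0.03,0.57,0.03,S,8,0
S_mediterranea,anandamide,100 uM,0.28,0.03,0.30,0.05,0.08,0.01,0.49,0.03,P,7,0
S_mediterranea,amputation,,0.40,0.09,0.44,0.09,0.17,0.09,0.62,0.18,S,77,1
S_mediterranea,peristalsis,,0.26,0.07,0.23,0.19,0.06,0.04,0.50,0.07,P,14,1
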