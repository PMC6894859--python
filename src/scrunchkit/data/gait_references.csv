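species,gait,parameter,mean,sd,n
D_japonica,scrunching,frequency,0.70,0.27,15
D_japonica,scrunching,max_elongation,0.50,0.08,15
D_japonica,scrunching,speed,0.34,0.12,15
D_japonica,scrunching,asymmetry,0.60,0.12,15
S_mediterranea,scrunching,frequency,0.40,0.09,77
S_mediterranea,scrunching,max_elongation,0.44,0.09,77
S_mediterranea,scrunching,speed,0.17,0.09,77
S_mediterranea,scrunching,asymmetry,0.62,0.18,77
S_mediterranea,peristalsis,frequency,0.26,0.07,14
S_mediterranea,peristalsis,max_elongation,0.23,0.19,14
S_mediterranea,peristalsis,speed,0.06,0.04,14
S_mediterranea,peristalsis,asymmetry,0.50,0.07,14
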