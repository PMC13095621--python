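segment,sex,n,mean,sd
L4_sup,male,19,1.32,0.70
L4_sup,female,14,1.35,0.41
L4_inf,male,19,1.77,0.56
L4_inf,female,14,2.06,0.43
L5_sup,male,19,1.33,0.71
L5_sup,female,14,1.25,0.44
L5_inf,male,19,1.89,0.73
L5_inf,female,14,1.98,0.69
S1_sup,male,19,0.63,0.65
S1_sup,female,14,0.44,0.25
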