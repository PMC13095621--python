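segment,sex,n,mean,sd
L4_sup,male,19,1.07,0.56
L4_sup,female,14,1.18,0.46
L4_inf,male,19,3.16,0.99
L4_inf,female,14,3.43,1.15
L5_sup,male,19,1.12,0.56
L5_sup,female,14,1.35,0.55
L5_inf,male,19,3.20,0.82
L5_inf,female,14,3.28,0.82
S1_sup,male,19,2.73,0.65
S1_sup,female,14,2.23,0.54
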