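segment,sex,uniform_concave,asymmetric_concave,flat_bottom,flat
L4_sup,male,0,0,11,8
L4_sup,female,0,1,8,5
L4_inf,male,11,0,8,0
L4_inf,female,10,0,4,0
L5_sup,male,0,0,11,8
L5_sup,female,2,0,9,3
L5_inf,male,5,0,14,0
L5_inf,female,5,0,9,0
S1_sup,male,13,0,6,0
S1_sup,female,7,0,7,0
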