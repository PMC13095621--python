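segment,sex,uniform_concave,asymmetric_concave,flat_bottom,flat
L4_sup,male,4,5,2,8
L4_sup,female,5,2,5,2
L4_inf,male,7,6,4,2
L4_inf,female,8,3,3,0
L5_sup,male,1,11,1,6
L5_sup,female,1,6,2,5
L5_inf,male,4,11,1,3
L5_inf,female,4,7,1,2
S1_sup,male,0,2,1,16
S1_sup,female,0,1,0,13
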