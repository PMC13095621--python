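segment,uniform_concave,asymmetric_concave,flat_bottom,flat
L4_sup,0,1,19,13
L4_inf,21,0,12,0
L5_sup,2,0,20,11
L5_inf,10,0,23,0
S1_sup,20,0,13,0
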