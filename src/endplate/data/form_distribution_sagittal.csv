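segment,uniform_concave,asymmetric_concave,flat_bottom,flat
L4_sup,9,7,7,10
L4_inf,15,9,7,2
L5_sup,2,17,3,11
L5_inf,8,18,2,5
S1_sup,0,3,1,29
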