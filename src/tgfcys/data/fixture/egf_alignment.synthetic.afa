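>LTBP1_EGF7
DEDCGGGGCGGGGGCGGGGGCGGGGGGCGGGGGGGCEDEGGG
>FBN1_EGF28
DEDCSSSSCSSSSSCSSSSSCSSSSSSCSSSSSSSCEDESSS
>FBN2_EGF22
DEDCTTTTCTTTTTCTTTTTCTTTTTTCTTTTTTTCEDETTT
>FBN3_EGF20
DEDCNNNNCNNNNNCNNNNNCNNNNNNCNNNNNNNCEDENNN
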