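>LTBP1_TB3
GCGGEGCGGGGDCGGGDCGGGGCGGGGGGGGGCFPGGGDCGEGGGCGG
>FBN1_TB6
SCSSSSCDSSSDCSSSSCSESSCSSSSSSSSSC--DSSSCSESSSCSS
>FBN2_TB6
TCTTTTCDTTTDCTTTTCTETTCTTTTTTTTTC--DTTTCTETTTCTT
>FBN3_TB6
NCNNNNCDNNNDCNNNNCNENNCNNNNNNNNNC--DNNNCNENNNCNN
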