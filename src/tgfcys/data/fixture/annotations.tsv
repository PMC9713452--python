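id	accession	subfamily	signal_start	signal_end	cleavage_pos
TGFB1	SYN-TGFB1	TGF-beta	1	29	278
TGFB2	SYN-TGFB2	TGF-beta	1	20	302
TGFB3	SYN-TGFB3	TGF-beta	1	23	280
AMH	SYN-AMH	TGF-beta	1	18	250
NODAL	SYN-NODAL	TGF-beta	1	26	280
GDF15	SYN-GDF15	TGF-beta	1	29	240
LEFTY1	SYN-LEFTY1	TGF-beta	1	21	270
LEFTY2	SYN-LEFTY2	TGF-beta	1	21	272
INHA	SYN-INHA	Activin	1	24	260
INHBA	SYN-INHBA	Activin	1	28	300
INHBB	SYN-INHBB	Activin	1	28	292
INHBC	SYN-INHBC	Activin	1	22	280
INHBE	SYN-INHBE	Activin	1	22	278
MSTN	SYN-MSTN	Activin	1	23	266
GDF11	SYN-GDF11	Activin	1	24	298
GDF3	SYN-GDF3	Activin	1	23	250
BMP2	SYN-BMP2	BMP	1	23	282
BMP3	SYN-BMP3	BMP	1	24	270
BMP4	SYN-BMP4	BMP	1	24	292
BMP5	SYN-BMP5	BMP	1	28	280
BMP6	SYN-BMP6	BMP	1	26	296
BMP7	SYN-BMP7	BMP	1	29	292
BMP8A	SYN-BMP8A	BMP	1	27	280
BMP8B	SYN-BMP8B	BMP	1	27	281
BMP10	SYN-BMP10	BMP	1	21	290
BMP15	SYN-BMP15	BMP	1	25	268
GDF1	SYN-GDF1	BMP	1	26	252
GDF2	SYN-GDF2	BMP	1	22	274
GDF5	SYN-GDF5	BMP	1	27	300
GDF6	SYN-GDF6	BMP	1	22	280
GDF7	SYN-GDF7	BMP	1	28	298
GDF9	SYN-GDF9	BMP	1	29	303
GDF10	SYN-GDF10	BMP	1	25	276
GDNF	SYN-GDNF	outgroup	1	19	230
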