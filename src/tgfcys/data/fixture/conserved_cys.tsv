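protein	region	position	label
AMH	ASSN	22	CYS@1
BMP2	ASSN	30	CYS@1
BMP4	ASSN	32	CYS@1
BMP6	ASSN	34	CYS@1
BMP7	ASSN	31	CYS@1
GDF11	ASSN	76	CYS@1
GDF11	ASSN	79	CYS@4
GDF2	ASSN	25	CYS@1
GDNF	ASSN	35	CYS@1
GDNF	ASSN	38	CYS@4
INHBA	ASSN	41	CYS@1
INHBA	ASSN	44	CYS@4
INHBB	ASSN	92	CYS@1
INHBB	ASSN	95	CYS@4
INHBC	ASSN	28	CYS@1
INHBC	ASSN	31	CYS@4
INHBE	ASSN	26	CYS@1
INHBE	ASSN	29	CYS@4
MSTN	ASSN	40	CYS@1
MSTN	ASSN	43	CYS@4
NODAL	ASSN	30	CYS@1
TGFB1	ASSN	33	CYS@1
TGFB2	ASSN	24	CYS@1
TGFB3	ASSN	27	CYS@1
AMH	B8	208	CYS@1
BMP10	B8	245	CYS@1
BMP15	B8	209	CYS@4
BMP2	B8	248	CYS@3
BMP4	B8	250	CYS@3
BMP5	B8	241	CYS@3
BMP6	B8	253	CYS@3
BMP7	B8	249	CYS@1
GDF1	B8	227	CYS@4
GDF2	B8	237	CYS@4
GDF5	B8	255	CYS@4
GDF6	B8	230	CYS@4
GDF7	B8	259	CYS@4
GDF9	B8	242	CYS@1
INHBA	B8	244	CYS@1
INHBA	B8	247	CYS@4
INHBB	B8	241	CYS@1
INHBB	B8	244	CYS@4
INHBC	B8	236	CYS@1
INHBC	B8	239	CYS@4
INHBE	B8	232	CYS@1
INHBE	B8	235	CYS@4
TGFB1	B8	223	CYS@1
TGFB1	B8	225	CYS@3
TGFB2	B8	254	CYS@1
TGFB2	B8	256	CYS@3
TGFB2	B8	257	CYS@4
TGFB3	B8	226	CYS@1
TGFB3	B8	228	CYS@3
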