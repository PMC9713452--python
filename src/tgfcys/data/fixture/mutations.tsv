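protein	position	ref	alt	phenotype	source	near_region	provenance
BMP15	209	C	G	Lung squamous cell neoplasms	GDC	0	results-text
GDF1	227	C	del:145	Right atrial isomerism	GDC	0	results-text
GDF6	230	C	R	Colon adenocarcinoma	GDC	0	results-text
GDF6	419	C	Y	Colon adenocarcinoma	GDC	0	results-text
GDF5	438	R	C	colon adenocarcinoma	GDC	1	results-text
INHBA	244	C	Y	Lung adenocarcinoma	GDC	0	results-text
TGFB1	223	C	R	Camurati-Engelmann disease	MalaCards	0	results-text
TGFB1	223	C	G	Camurati-Engelmann disease	MalaCards	0	results-text
TGFB1	223	C	S	Camurati-Engelmann disease	MalaCards	0	results-text
TGFB1	225	C	R	Camurati-Engelmann disease	MalaCards	0	results-text
TGFB1	225	C	Y	Camurati-Engelmann disease	MalaCards	0	results-text
INHBE	29	C	Y	Plasma cell tumors	GDC	0	results-text
INHBB	154	S	C	plasma cell tumors	GDC	1	results-text
TGFB2	256	C	*	Endometrial adenocarcinoma	GDC	0	results-text
INHA	291	C	W	endometrial adenocarcinoma	GDC	0	results-text
INHBB	223	R	C	endometrial adenomas	GDC	1	results-text
TGFB2	257	C	F	Holt-Oram syndrome	GDC	0	results-text
TGFB2	378	C	Y	Holt-Oram syndrome	GDC	0	results-text
TGFB2	257	C	*	Loeys-Dietz syndrome	GDC	0	results-text
TGFB2	439	C	S	Loeys-Dietz syndrome	GDC	0	results-text
TGFB3	409	C	Y	Loeys-Dietz syndrome	GDC	0	results-text
TGFB2	246	C	Y	Lung adenocarcinoma	GDC	0	results-text
TGFB2	407	C	S	Lung adenocarcinoma	GDC	0	results-text
LTBP1	1022	C	Y	plasma cell tumors	GDC	0	results-text
FBN1	1431	C	Y	plasma cell tumors	GDC	0	results-text
FBN1	1687	C	F	plasma cell tumors	GDC	0	results-text
FBN2	1193	C	S	plasma cell tumors	GDC	0	table-transcription
FBN2	1378	C	S	plasma cell tumors	GDC	0	table-transcription
FBN2	1406	C	F	plasma cell tumors	GDC	0	results-text
FBN2	1579	C	G	plasma cell tumors	GDC	0	results-text
FBN2	1608	C	Y	plasma cell tumors	GDC	0	results-text
FBN3	142	C	R	plasma cell tumors	GDC	0	table-transcription
FBN3	1101	C	Y	plasma cell tumors	GDC	0	table-transcription
FBN3	1519	C	R	plasma cell tumors	GDC	0	results-text
LTBP1	559	C	Y	colon adenocarcinoma	GDC	0	results-text
LTBP1	594	C	W	colon adenocarcinoma	GDC	0	results-text
LTBP2	330	C	R	colon adenocarcinoma	GDC	0	table-transcription
FBN1	480	C	Y	colon adenocarcinoma	GDC	0	table-transcription
FBN1	1120	C	S	colon adenocarcinoma	GDC	0	table-transcription
FBN1	1900	C	F	colon adenocarcinoma	GDC	0	table-transcription
FBN2	602	C	W	colon adenocarcinoma	GDC	0	table-transcription
FBN2	890	C	Y	colon adenocarcinoma	GDC	0	table-transcription
FBN2	1406	C	S	colon adenocarcinoma	GDC	0	results-text
FBN3	260	C	Y	colon adenocarcinoma	GDC	0	table-transcription
FBN3	770	C	S	colon adenocarcinoma	GDC	0	table-transcription
FBN3	1450	C	R	colon adenocarcinoma	GDC	0	table-transcription
LTBP1	1337	C	R	endometrial adenocarcinoma	GDC	0	table-transcription
LTBP2	410	C	Y	endometrial adenocarcinoma	GDC	0	table-transcription
LTBP2	612	C	S	endometrial adenocarcinoma	GDC	0	table-transcription
LTBP2	845	C	F	endometrial adenocarcinoma	GDC	0	table-transcription
LTBP2	1010	C	R	endometrial adenocarcinoma	GDC	0	table-transcription
LTBP3	1215	C	S	endometrial adenocarcinoma	GDC	0	table-transcription
LRC32	342	C	R	endometrial adenocarcinoma	GDC	0	results-text
SELE	520	C	G	endometrial adenocarcinoma	GDC	0	table-transcription
FBN1	720	C	Y	endometrial adenocarcinoma	GDC	0	table-transcription
FBN1	1530	C	S	endometrial adenocarcinoma	GDC	0	table-transcription
FBN1	1760	C	W	endometrial adenocarcinoma	GDC	0	table-transcription
FBN1	1950	C	R	endometrial adenocarcinoma	GDC	0	table-transcription
FBN2	1240	C	Y	endometrial adenocarcinoma	GDC	0	table-transcription
FBN2	1335	C	S	endometrial adenocarcinoma	GDC	0	table-transcription
FBN3	950	C	F	endometrial adenocarcinoma	GDC	0	table-transcription
FBN3	1575	C	Y	endometrial adenocarcinoma	GDC	0	table-transcription
FBN1	1431	C	W	Loeys-Dietz syndrome	GDC	0	results-text
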