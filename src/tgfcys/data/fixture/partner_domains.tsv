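partner	kind	ordinal	start	end
LTBP1	TB8CYS	1	540	600
LTBP1	EGF	7	1000	1040
LTBP1	TB8CYS	3	1330	1392
LTBP2	TB8CYS	1	300	360
LTBP2	EGF	5	400	440
LTBP2	EGF	9	600	640
LTBP2	EGF	14	830	870
LTBP2	TB8CYS	3	990	1050
LTBP3	TB8CYS	3	1200	1260
LTBP4	TB8CYS	3	1290	1350
FBN1	EGF	8	470	510
FBN1	EGF	24	1410	1450
FBN1	EGF	28	1670	1710
FBN1	TB8CYS	6	1830	1890
FBN2	EGF	16	1180	1220
FBN2	EGF	22	1370	1410
FBN2	TB8CYS	6	1560	1620
FBN3	EGF	2	130	170
FBN3	EGF	20	1080	1120
FBN3	TB8CYS	6	1490	1550
LRC32	LRR	7	205	230
LRC32	LRR	12	330	355
LRC33	LRR	10	280	305
SELE	SUSHI	5	500	560
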