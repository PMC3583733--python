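name	synonyms	rs_id	pos_hg18	pos_hg19	conversion
M100	P901	rs9000100	1100	100	A->G
M110			1150	150	C->T
M111	P911,Page11	rs9000111	1200	200	G->A
M200			1250	250	T->C
M300	P903		1300	300	A->C
M310			1350	350	C->G
M320			1400	400	G->T
M322			1450	450	T->A
M325			1500	500	A->T
L999	PL9		1600	600	C->A
M17		rs3908	1700	700	4G->3G
V218			1750	750	G->A
M900			1800		C->T
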