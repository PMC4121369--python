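nuid	gene	chromosome	start	end	strand	fc_all	p_all	fc_males	p_males	fc_females	p_females
fVedl_tOxJHgKDgkUk	ANGPTL7	1	11255703	11255752	+	0.17	1.11E-16	0.17	5.11E-15	0.17	2.00E-16
Zl4IEsHlNCOIgeii9c	VCAM1	1	101204019	101204068	+					0.12	1.78E-08
cqSF81At6xB7XyHjiQ	PRG4	1	186282872	186282921	+					0.2	2.00E-16
lojns5Hg3o6bW_X07g	CFH	1	196648872	196648921	+					0.23	1.43E-07
Qo0T0_REI6OtlJLFOU	CFH	1	196658692	196658741	+					0.38	1.11E-16
NIDSs_kv.U.0.u7g.8	H3F3A	1	226259333	226259382	+			0.33	7.90E-07
NfqgAIRfuk8Lfn_vAk	EXOC8	1	231468728	231468777	-			0.21	1.68E-07
ZoXhLA6oEHo3o160B8	EPCAM	2	47606943	47606992	+					0.69	1.11E-16
BnrvPnvPuvuuMkvvno	EPCAM	2	47607046	47607095	+					1.04	2.26E-08
cpAs4gp4jAojq4jkyo	EPCAM	2	47612328	47612349	+	0.2	1.65E-09	0.2	2.98E-07	0.21	2.00E-16
xd6Z60LRKEWCAU0bEY	EFEMP1	2	56149495	56149544	-			0.39	6.29E-10
9l31SOkN7XN3uegjnI	AOX1	2	201535434	201535483	+					0.08	2.00E-16
Zl7s26IBCIUH.09XlU	COL6A3	2	238232942	238232991	-					0.39	6.62E-14
QXNDUD1d6L9O85e_Sk	COL6A3	2	238233095	238233144	-					0.13	6.77E-10
rItcu7lcV6dKfep3iA	CAMP	3	48266905	48266954	+	0.2	2.00E-16	0.2	2.00E-16	0.2	2.00E-16
69KffSiAkLEesX6HuQ	SLC25A20	3	48900042	48900091	-			0.36	5.69E-11
lnxCeHgiilejtJhR.U	DNASE1L3	3	58179070	58179093	-					0.13	2.00E-16
6h.tJeHqxD3.vD_S7o	PHLDB2	3	111694722	111694770	+					0.27	3.50E-09
ommprt5mtriFZmriGc	FAIM	3	138327937	138327986	+					0.11	3.54E-07
ln0vn7fesf3vOp.6ok	TP63	3	189614936	189614985	+					0.21	2.00E-16
KpJwqU0.HokiEUlMrU	NULL	4	144496759	144496808	-					0.09	5.31E-07
35QRHIUd.o9CJHuzh4	GPX8	5	54460446	54460495	+					0.15	2.00E-16
riWe5en0.0i4hP7Huk	BTNL9	5	180488062	180488111	+					0.2	3.57E-12
QfyhEl_TCJbggfqkvk	LOC401233	6	3019504	3019553	-			0.15	7.79E-07
fajeo6Sh6PMkUgoxnk	BMP5	6	55625255	55625272	-	0.19	2.30E-14	0.18	7.69E-12	0.19	2.00E-16
K6oCu8IOLU3SUMufrs	TBX18	6	85444495	85444544	-					0.12	6.56E-07
07q5ey9ScdKKeKSiDg	IKBIP	6	168224491	168224540	-			-0.69	2.87E-07
0uHF8y.yziXFfoICwo	TMEM196	7	19759195	19759244	-					0.21	4.12E-09
Zn50ZUiIgAvCeeFeCk	INMT	7	30797037	30797086	+					0.12	3.31E-12
cyxSgtKKIa_cDsvc3o	LOC441208	7	32768986	32769035	+	0.32	2.00E-16	0.33	2.00E-16	0.32	7.88E-15
iX3qB7qexxL0p66.jk	FGL2	7	76825768	76825817	-					0.43	2.49E-11
KmAXs1qVBeAE1SUIHo	COL1A2	7	94057677	94057726	+					0.35	2.00E-16
9jUT7yueFyEiOB4rX4	COL1A2	7	94060111	94060160	+					0.45	2.00E-16
QyCF6hIoee3ld3rRXk	DEFA1	8	6856660	6856709	-	0.12	1.38E-13	0.12	1.57E-12	0.12	1.11E-15
xKBJBHXp4QcJQzpXK0	SCARA5	8	27727946	27727995	-					0.26	9.82E-07
0LiHngASd5JSA633Ro	SDCBP	8	59492276	59492306	+					0.15	6.15E-07
K7con83.RdfSKOc6rU	BNC2	9	16416697	16416746	-					0.17	1.83E-13
6oXSUI4JlkkvBc4W5I	CCL19	9	34689927	34689940	-					0.32	2.00E-16
WrlIsC.cAwT13R_xVE	OGN	9	95146774	95146823	-					0.77	4.11E-15
BDhFLxNahZPgiMZeio	OGN	9	95147978	95148027	-					0.88	2.00E-16
ZjdFPOE1NVcnRRMkTI	OMD	9	95176881	95176930	-					0.45	3.73E-07
Kc4qiig6iKqdKpQwHc	SLC27A4	9	131123437	131123486	+					0.09	3.26E-08
oKAoV4glIpSToLgqkg	ITIH2	10	7788602	7788651	+					0.2	1.24E-09
lqMskrfH4OAt4z_eOk	OTUD1	10	23730535	23730584	+					0.16	9.87E-11
xqKT0lF6D5OJ2dL_o8	PDE6H	12	15134355	15134404	+					0.16	2.54E-08
ZfKOiSBOiKCP0.wnXU	SLCO1C1	12	20905935	20905984	+			0.13	2.83E-10
fX9eh..pR5XocuAg6E	PKP2	12	32944450	32944499	-					0.21	2.92E-07
cjif7cfQC.v58VfSXU	GJB2	13	20761910	20761959	-					1	2.00E-16
ciAGgiIoDiuq_igFTo	EDNRB	13	78470881	78470930	-	0.18	1.49E-07			0.18	1.11E-16
xuigGSeQeCaIdwFSfk	PTGDR	14	52742862	52742911	+					0.15	2.00E-16
rl55P5uN0IXUlILV9Q	PTGDR	14	52743020	52743069	+					0.32	2.00E-16
0knRyVFXXc.6sIg.HE	TMEM30B	14	61744888	61744937	-					0.45	2.00E-16
TP6d2kdUp6iejF5XpI	LOC388152	15	84871644	84871693	-					0.12	5.26E-09
3eh0.Qkv5.70DbjiAU	NUDT21	16	56463489	56463538	-	0.15	1.04E-07	0.15	6.69E-08	0.15	5.92E-07
KsuX1EryiLsDi3rL_0	TMEM220	17	10617182	10617231	-	0.09	2.07E-08	0.09	2.60E-09	0.08	3.79E-08
x.Sd_F7Vd6eXeLeDdU	TOP2A	17	38545067	38545116	-	0.11	1.49E-07			0.12	2.00E-16
EnpItS.SAMZeiUiS2E	FAM20A	17	66533566	66533615	-	0.12	2.70E-08	0.12	4.20E-09
9k3mzbqMPhOKn4iB1I	CD177	19	43867372	43867421	+	0.14	6.18E-14	0.13	8.74E-12	0.14	2.00E-16
3CBVEhgxeipOOJilWo	MYL9	20	35176437	35176486	+					0.11	1.34E-07
No174RVAVBCigl6guU	SLPI	20	43882216	43882241	-					0.27	2.00E-16
ojLV_BETnlid6ABVEk	UBE2C	20	44444504	44444552	+					0.1	2.00E-16
r37yu690k8Sk.uedqI	LOC401397	20	57523176	57523225	-					0.11	2.69E-08
TdSCif1KMn_KMJ5o4k	LOC96610	22	22664198	22664247	+					0.09	6.12E-08
luuljtLxeOlOiCJCmE	ADRBK2	22	25817204	25817253	+					0.1	1.11E-16
TADKWp66dGXsNUkf6Q	GGA1	22	38013841	38013890	+	-0.83	9.84E-07	-0.86	2.61E-09
Z5K0omXVEuL9VRHadc	RRP7A	22	42907975	42908024	-					0.08	2.00E-16
EqZLp0Zez1SR.qKUKQ	RRP7B	22	42969512	42969561	-					-0.55	6.55E-10
0szegLje1eiuskL9Ro	NPM1	X	123414788	123414837	+			0.2	8.35E-08
lLh40p.7RHpRI4TceU	GYG2P1	Y	14518992	14518993	-					0.11	1.21E-07
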