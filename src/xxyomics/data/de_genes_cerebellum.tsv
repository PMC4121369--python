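nuid	gene	chromosome	start	end	strand	fc_all	p_all	fc_males	p_males	fc_females	p_females
uO7tSXg9R5ohX55GF4	TNFRSF18	1	1140794	1140843	-					0.15	1.01E-14
TQ5MLOicLl.6KP36CI	FAM76A	1	28087875	28087924	+					0.07	2.70E-07
3VHqE.9440_ek4J75o	PCNXL2	1	233275460	233275463	-					0.14	6.48E-12
ZoXhLA6oEHo3o160B8	EPCAM	2	47606943	47606992	+					0.54	5.47E-12
BnrvPnvPuvuuMkvvno	EPCAM	2	47607046	47607095	+					0.9	3.44E-13
6KDbq30yk7941631Kg	KCNH7	2	163228344	163228393	-					0.12	7.42E-07
6R96hdG6D63d4rLojk	LOC401052	3	10048205	10048254	-					0.22	1.16E-10
TQeEon6idqJ_oip878	ARPP21	3	35722564	35722613	+					0.1	1.46E-12
rItcu7lcV6dKfep3iA	CAMP	3	48266905	48266954	+	0.09	3.46E-12	0.09	1.86E-09	0.1	2.00E-16
QEKvDrJSV50hXQ4Rno	ANKRD17	4	74005263	74005312	-					0.22	1.98E-07
0q44on0oRTyiSnoQTc	SH3TC2	5	148384360	148384409	-					0.1	5.29E-11
WVElhxxViAlxN9F9ec	RASGEF1C	5	179564876	179564899	-			0.13	4.15E-07
01Xd110F6gx9ITdQHQ	RNF39	6_mcf_hap5	1420068	1420117	-					0.16	6.29E-07
0cVOsh0SeXuuB.p1eU	PRRC2A	6_dbb_hap3	2890088	2890137	+					0.35	2.22E-07
Tqg7v6gLQi6yj6_nqY	C6orf132	6	42070437	42070486	-					0.23	3.15E-10
HqI33tUcoB5g_xRIqI	C6orf176	6	166338009	166338058	-					0.11	1.15E-08
cyxSgtKKIa_cDsvc3o	LOC441208	7	32768986	32769035	+	0.14	3.61E-07
cyxSgtKKIa_cDsvc3o	LOC441208	7	32768986	32769035	+					0.15	2.00E-16
3WfZR.WSd6.5x7nndc	C7orf52	7	100813863	100813912	-	0.15	4.28E-09	0.15	1.03E-08	0.14	1.43E-09
K_N4laRVOKE5IkXkig	CNTFR	9	34552159	34552166	-	0.23	2.00E-16	0.23	3.99E-14	0.23	2.00E-16
uJdPSKuSnCZOhiSaug	GPSM1	9	139252547	139252596	+					0.25	2.95E-08
90NSdfgVdSVn0l6k0c	ENTPD2	9	139942751	139942800	-					0.09	6.35E-08
3Z2Vqi1Jrte6J5ZTpU	IL15RA	10	6019449	6019498	-	0.08	8.68E-07			0.08	6.27E-08
ZIRQ6g1Q6oLY56590U	IGF2	11	2159459	2159460	-	0.1	9.90E-14	0.09	1.45E-12	0.1	2.00E-16
Wl36k3qhE6w57l_Egs	CALCA	11	14988290	14988339	-	0.23	8.30E-09	0.23	5.73E-09	0.22	5.94E-09
x9f4JKzfk6VFquC1eU	TMEM223	11	62558209	62558258	-					0.28	6.22E-07
9ooIoDrhULuqvuvSgI	SLC22A6	11	62744143	62744192	-	0.18	3.65E-07	0.18	9.29E-07	0.18	9.39E-08
Z9IldVfociaepInc.BI	CNIH2	11	66051236	66051285	+	0.35	9.53E-07			0.36	4.88E-15
HFwXl7tTpgV3E1wXlo	SMARCC2	12	56558210	56558259	-	0.18	8.81E-08	0.19	4.36E-08	0.18	6.14E-07
QO_wesnjwsy9XkVfeo	LOC220115	13	53161055	53161104	+			0.12	8.32E-09
c70LXLcyj6S.A5.HVU	OLFM4	13	53626107	53626156	+	0.09	4.37E-07	0.09	1.59E-07
36JWb571RKl2v.XB_c	SPSB3	16	1826791	1826840	-					-0.89	9.17E-07
BloWN0NHoOuep7agcE	TNRC6A	16	24834917	24834966	+	0.13	9.96E-09	0.13	1.69E-08	0.13	9.43E-09
QLR0VHu.euUKd_KlUc	FAM64A	17	6354072	6354121	+					0.1	1.33E-07
EdOgRNRCeCkhClZIJ0	RPL19	17	37360385	37360427	+					0.7	6.11E-08
x6gXnXotNXeQEiJUi4	RBFOX3	17	77303806	77303842	-					0.57	2.85E-09
iIoD3lFP9UreSVdSeo	RBFOX3	17	77303839	77303888	-					0.3	3.77E-07
f4oYbqlTz8YVp9fc6U	FN3K	17	80708373	80708422	+	0.22	1.29E-10	0.21	7.08E-10	0.23	1.34E-14
x3S.SNd5j.Pi6At_Z4	MGC70870	17_gl000205_random	119141	119190	+					0.31	3.30E-07
oCVdUCZaWHZ7dnqh38	NFIC	19	3463515	3463564	+					0.1	1.67E-08
QudxDtFe.RtNJF3qhU	OLFM2	19	9964866	9964915	-	0.54	9.61E-07	0.57	1.20E-08
9RSiJQISr7l8VSiUVc	NACC1	19	13251492	13251541	+	0.49	7.50E-11	0.49	1.49E-08	0.5	2.00E-16
uCKpSOEVwJKeNqQ6is	RAB3A	19	18307891	18307940	-					0.93	1.71E-12
l3roFeVfFJfjpJqDes	POU2F2	19	42595686	42595735	-					0.09	6.52E-08
T3DouuhUIkzS5yQDpI	UBE2V1	20	48700666	48700677	-					0.19	8.02E-09
uXOOCKm1HogpVesKUk	KIAA1647	22	18958144	18958171	+					0.12	6.51E-07
i1_RF4d7R0Jf3UUpV0	SERPIND1	22	21141675	21141724	+					0.1	4.00E-07
Z5K0omXVEuL9VRHadc	RRP7A	22	42907975	42908024	-					0.16	4.44E-15
EU_ve.pMFc8DrmSJ4M	LOC389834	Un_gl000218	51064	51113	-			0.14	1.87E-07
lt1Hf71dcOcPygIhR4	CHIC1	X	72903733	72903782	+					0.08	4.14E-06
WnUxEZ5faxUURBNQuk	L1CAM	X	153127445	153127494	-					0.77	1.28E-05
HLEukIKIKKaSqkOEnQ	L1CAM	X	153128160	153128209	-					0.08	2.23E-05
fKg7fXeNt9dKDIdCzk	RPS4Y1	Y	2712151	2712200	+			1.48	2.00E-16
Q8jADkAqS017VJIV90	NLGN4Y	Y	16953254	16953303	+			0.06	1.27E-08
6tUwTEFxS.3kFYCVKk	AL833666	Y	21724080	21724129	-			0.18	3.20E-10
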