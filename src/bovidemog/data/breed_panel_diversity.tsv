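abb	breed	tax	dataset	n	ho	fis
ABO	Abondance	taurus	2	22	0.308	0.089
ANG	Angus	taurus	1	61	0.305	0.098
AUB	Aubrac	taurus	2	22	0.301	0.112
BPN	Bretonne black pied	taurus	2	18	0.317	0.064
BRU	French brown swiss	taurus	2	18	0.288	0.150
BSW	Brown swiss	taurus	1	24	0.280	0.171
CHA	Charolais	taurus	1	20	0.314	0.071
CHL	Charolais	taurus	2	26	0.320	0.054
GAS	Gascon	taurus	2	22	0.305	0.100
GNS	Guernsey	taurus	1	21	0.275	0.188
HFD	Hereford	taurus	1	31	0.304	0.101
HO2	Holstein	taurus	2	31	0.316	0.066
HOf	Holstein	taurus	1	30	0.313	0.077
HOL	Holstein	taurus	2	64	0.319	0.057
JE2	Jersey	taurus	2	28	0.263	0.223
JEf	Jersey	taurus	1	21	0.277	0.180
JER	Jersey	taurus	2	28	0.263	0.223
LMS	Limousin	taurus	1	44	0.309	0.086
MAN	Maine-Anjou	taurus	2	16	0.303	0.105
MAR	Maraichine	taurus	2	19	0.318	0.059
MON	Montbeliarde	taurus	2	30	0.299	0.116
NOR	Normande	taurus	2	30	0.307	0.094
NRC	Norwegian red cattle	taurus	1	21	0.317	0.063
OUL	Oulmes Zaer	taurus	2	27	0.288	0.149
PMT	Piedmontese	taurus	1	24	0.321	0.053
PRP	French red pied lowland	taurus	2	22	0.325	0.039
RGU	Red Angus	taurus	1	15	0.305	0.100
RMG	Romagnola	taurus	1	24	0.291	0.141
ROM	Romagnola	taurus	3	13	0.293	0.134
CHI	Chianina	taurus	3	14	0.285	0.158
CIL	Chillingham	taurus	3	16	0.026	0.924
W_P	White park	taurus	3	15	0.245	0.276
SAL	Salers	taurus	2	22	0.285	0.157
TAR	Tarine	taurus	2	18	0.300	0.113
VOS	Vosgienne	taurus	2	20	0.312	0.078
BAO	Baoule	taurus	2	29	0.216	0.362
LAG	Lagune	taurus	2	30	0.183	0.460
NDA	N'Dama	taurus	1	25	0.209	0.381
ND1	N'Dama	taurus	2	14	0.235	0.307
ND2	N'Dama	taurus	2	17	0.237	0.299
ND3	N'Dama	taurus	2	25	0.210	0.381
SOM	Somba	taurus	2	30	0.217	0.359
BRM	Brahman	indicus	1	25	0.190	0.440
GIR	Gir	indicus	1	24	0.160	0.528
NEL	Nelore	indicus	1	21	0.161	0.524
ZBO	Zebu Bororo	indicus	2	23	0.240	0.292
ZFU	Zebu Fulani	indicus	2	30	0.241	0.289
ZMA	Zebu from Madagascar	indicus	2	30	0.194	0.427
BMA	Beefmaster	hybrid	1	24	0.328	0.031
SGT	Santa Gertrudis	hybrid	1	24	0.313	0.075
BOR	Borgou	hybrid	2	30	0.263	0.222
KUR	Kuri	hybrid	2	30	0.261	0.229
SHK	Sheko	hybrid	1	20	0.250	0.260
SIM	Simmental	taurus	1	3
GBV	Gelbvieh	taurus	1	3
OBB	North American Bison	bison	2	4
OBJ	Banteng	javanicus	1	2
OGR	Gaur	gaurus	1	4
OYK	Yak	grunniens	1	2
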