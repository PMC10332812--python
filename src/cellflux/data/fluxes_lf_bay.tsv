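type	pathway	id	reaction	flux	lb	ub
NET	transport	GLUT	GLC.x (abcdef) -> GLC (abcdef)	8.80E+02	8.80E+02	8.80E+02
NET	transport	PYRR	PYR.x (abc) -> PYR.c (abc)	6.06E+01	6.06E+01	6.06E+01
NET	transport	MCT	LAC (abc) <-> LAC.x (abc)	1.33E+03	1.33E+03	1.33E+03
NET	transport	ALAR	ALA (abc) -> ALA.x (abc)	5.98E+00	5.88E+00	6.24E+00
NET	transport	GLNR	GLN.x (abcde) -> GLN (abcde)	2.06E+01	2.06E+01	2.06E+01
NET	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	1.68E+01	1.68E+01	1.68E+01
NET	transport	ASPR	ASP (abcd) -> ASP.x (abcd)	1.80E+00	1.80E+00	1.81E+00
NET	transport	SERR	SER.x (abc) -> SER (abc)	2.50E+00	2.50E+00	2.50E+00
NET	transport	CYSR	CYX.x (abcdef) -> CYS (abc) + CYS (def)	3.07E-01	3.06E-01	3.07E-01
NET	transport	GLYR	GLY (ab) -> GLY.x (ab)	5.52E-01	4.30E-01	7.45E-01
NET	glycolysis	HK	GLC (abcdef) -> G6P (abcdef)	8.80E+02	8.80E+02	8.80E+02
NET	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	8.42E+02	8.42E+02	8.42E+02
NET	glycolysis	PFK	F6P (abcdef) -> FBP (abcdef)	8.65E+02	8.65E+02	8.65E+02
NET	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	8.65E+02	8.65E+02	8.65E+02
NET	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	8.65E+02	8.65E+02	8.65E+02
NET	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	1.74E+03	1.74E+03	1.74E+03
NET	glycolysis	ENO	3PG (abc) -> PEP (abc)	1.57E+03	1.57E+03	1.57E+03
NET	glycolysis	PK	PEP (abc) -> PYR.c (abc)	1.65E+03	1.65E+03	1.65E+03
NET	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	1.33E+03	1.33E+03	1.33E+03
NET	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	9.36E+00	9.32E+00	9.42E+00
NET	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	2.28E-07	-1.22E-05	6.41E-04
NET	ppp	G6PD	G6P (abcdef) -> P5P (bcdef) + CO2 (a)	3.64E+01	3.64E+01	3.64E+01
NET	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	1.17E+01	1.17E+01	1.17E+01
NET	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	1.17E+01	1.17E+01	1.17E+01
NET	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	1.17E+01	1.17E+01	1.17E+01
NET	anaplerosis	PYRT	PYR.c (abc) -> PYR.m (abc)	5.50E+02	5.50E+02	5.50E+02
NET	anaplerosis	PC	PYR.m (abc) + CO2 (d) -> OAC (abcd)	9.05E+01	9.05E+01	9.05E+01
NET	anaplerosis	PEPCK	OAC (abcd) -> PEP (abc) + CO2 (d)	8.58E+01	8.58E+01	8.58E+01
NET	anaplerosis	ME2	MAL (abcd) -> PYR.m (abc) + CO2 (d)	1.00E-07	0.00E+00	9.49E-06
NET	anaplerosis	ME1	MAL (abcd) -> PYR.c (abc) + CO2 (d)	1.00E-07	0.00E+00	2.15E-05
NET	anaplerosis	FAO	FAO.src (ab) -> AcCoA.m (ab)	1.09E-04	8.34E-06	4.14E-02
NET	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	-2.46E-01	-2.47E-01	-2.46E-01
NET	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	1.88E+01	1.88E+01	1.88E+01
NET	tca	PDH	PYR.m (abc) -> AcCoA.m (bc) + CO2 (a)	4.60E+02	4.60E+02	4.60E+02
NET	tca	CS	AcCoA.m (ef) + OAC (abcd) -> CIT (dcbfea)	4.60E+02	4.60E+02	4.60E+02
NET	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	1.45E+01	1.45E+01	1.45E+01
NET	tca	OGDH	AKG (abcde) -> SUC (bcde) + CO2 (a)	1.43E+01	1.43E+01	1.43E+01
NET	tca	SDH	SUC (abcd) <-> FUM (abcd)	1.43E+01	1.43E+01	1.43E+01
NET	tca	FH	FUM (abcd) <-> MAL (abcd)	1.43E+01	1.43E+01	1.43E+01
NET	tca	MDH	MAL (abcd) <-> OAC (abcd)	4.60E+02	4.60E+02	4.60E+02
NET	tca	GOT	OAC (abcd) <-> ASP (abcd)	4.46E+00	4.46E+00	4.46E+00
NET	amino	PST	3PG (abc) -> SER (abc)	1.73E+02	1.73E+02	1.73E+02
NET	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	2.85E+00	2.79E+00	2.93E+00
NET	amino	CYST	SER (abc) <-> CYS (abc)	2.03E-01	2.02E-01	2.03E-01
NET	amino	SD	SER (abc) -> PYR.c (abc)	1.70E+02	1.70E+02	1.70E+02
NET	amino	GLYS	CO2 (a) + MEETHF (b) -> GLY (ab)	1.41E+00	1.30E+00	1.46E+00
NET	biomass	BIOMASS	1216*AcCoA.c + 295.6*ALA + 232.4*ASP + 114.7*CO2 + 71.43*CYS + 57.14*DHAP + 142.4*G6P + 158.6*GLN + 190.1*GLU + 324.2*GLY + 125.6*MEETHF + 114.7*P5P + 217.2*SER -> biomass	1.14E-02	1.14E-02	1.14E-02
NET	biomass	ACL	CIT (abcdef) -> AcCoA.c (ed) + MAL (fcba)	4.45E+02	4.45E+02	4.45E+02
NET	biomass	LIPS	AcCoA.c (ab) -> lipid (ab)	4.32E+02	4.32E+02	4.32E+02
NET	mixing	cPYR	0*PYR.c (abc) -> PYR.ms (abc)	1.00E-07	0.00E+00	1.00E+00
NET	mixing	mPYR	0*PYR.m (abc) -> PYR.ms (abc)	1.00E+00	0.00E+00	1.00E+00
NET	mixing	sPYR	PYR.ms (abc) -> PYR.fix (abc)	1.00E+00	1.00E+00	1.00E+00
EXCH	transport	MCT	LAC (abc) <-> LAC.x (abc)	7.11E+02	7.11E+02	7.11E+02
EXCH	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	3.48E+00	3.48E+00	3.48E+00
EXCH	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	4.31E+06	4.31E+06	4.31E+06
EXCH	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	1.02E+03	1.02E+03	1.02E+03
EXCH	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	7.57E+03	7.57E+03	7.57E+03
EXCH	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	1.09E+02	1.07E+02	1.09E+02
EXCH	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	4.92E+01	4.91E+01	4.94E+01
EXCH	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	2.45E+03	2.45E+03	2.45E+03
EXCH	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	1.00E-07	0.00E+00	1.20E-05
EXCH	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	1.00E+07	-Inf	Inf
EXCH	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	5.10E+01	5.10E+01	5.10E+01
EXCH	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	1.00E-07	0.00E+00	1.56E-04
EXCH	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	1.42E+03	1.42E+03	1.42E+03
EXCH	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	5.52E-01	5.51E-01	5.55E-01
EXCH	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	4.66E+00	4.66E+00	4.66E+00
EXCH	tca	SDH	SUC (abcd) <-> FUM (abcd)	1.04E+04	1.04E+04	1.04E+04
EXCH	tca	FH	FUM (abcd) <-> MAL (abcd)	4.56E+06	4.56E+06	4.56E+06
EXCH	tca	MDH	MAL (abcd) <-> OAC (abcd)	1.00E-07	0.00E+00	6.30E-03
EXCH	tca	GOT	OAC (abcd) <-> ASP (abcd)	4.76E+05	4.76E+05	4.76E+05
EXCH	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	1.86E+03	1.86E+03	1.86E+03
EXCH	amino	CYST	SER (abc) <-> CYS (abc)	1.33E-01	1.33E-01	1.33E-01
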