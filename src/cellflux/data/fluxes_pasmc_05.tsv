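type	pathway	id	reaction	flux	lb	ub
NET	transport	GLUT	GLC.x (abcdef) -> GLC (abcdef)	3.65E+02	3.65E+02	3.65E+02
NET	transport	PYRR	PYR.x (abc) -> PYR.c (abc)	4.53E+01	4.31E+01	4.57E+01
NET	transport	MCT	LAC (abc) <-> LAC.x (abc)	6.49E+02	6.49E+02	6.49E+02
NET	transport	ALAR	ALA (abc) -> ALA.x (abc)	7.83E+00	7.83E+00	8.24E+00
NET	transport	GLNR	GLN.x (abcde) -> GLN (abcde)	1.77E+02	1.77E+02	1.77E+02
NET	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	1.19E+01	1.19E+01	1.22E+01
NET	transport	ASPR	ASP (abcd) -> ASP.x (abcd)	6.92E+00	6.84E+00	7.00E+00
NET	transport	SERR	SER.x (abc) -> SER (abc)	2.57E+00	2.55E+00	2.57E+00
NET	transport	CYSR	CYX.x (abcdef) -> CYS (abc) + CYS (def)	3.75E+00	3.75E+00	3.75E+00
NET	transport	GLYR	GLY (ab) -> GLY.x (ab)	4.06E-01	3.86E-01	4.25E-01
NET	glycolysis	HK	GLC (abcdef) -> G6P (abcdef)	3.65E+02	3.65E+02	3.65E+02
NET	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	3.62E+02	3.62E+02	3.63E+02
NET	glycolysis	PFK	F6P (abcdef) -> FBP (abcdef)	3.61E+02	3.60E+02	3.61E+02
NET	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	3.61E+02	3.60E+02	3.61E+02
NET	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	3.60E+02	3.60E+02	3.60E+02
NET	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	7.21E+02	7.21E+02	7.21E+02
NET	glycolysis	ENO	3PG (abc) -> PEP (abc)	7.20E+02	7.20E+02	7.20E+02
NET	glycolysis	PK	PEP (abc) -> PYR.c (abc)	9.24E+02	9.24E+02	9.24E+02
NET	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	6.49E+02	6.49E+02	6.49E+02
NET	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	-1.36E+01	-1.39E+01	-1.35E+01
NET	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	2.62E+01	2.51E+01	2.65E+01
NET	ppp	G6PD	G6P (abcdef) -> P5P (bcdef) + CO2 (a)	1.16E-07	0.00E+00	1.10E-03
NET	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	-6.15E-01	-6.15E-01	-5.77E-01
NET	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	-6.15E-01	-6.15E-01	-5.77E-01
NET	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	-6.15E-01	-6.15E-01	-5.77E-01
NET	anaplerosis	PYRT	PYR.c (abc) -> PYR.m (abc)	3.36E+02	3.36E+02	3.36E+02
NET	anaplerosis	PC	PYR.m (abc) + CO2 (d) -> OAC (abcd)	2.37E+02	2.36E+02	2.37E+02
NET	anaplerosis	PEPCK	OAC (abcd) -> PEP (abc) + CO2 (d)	2.03E+02	2.03E+02	2.04E+02
NET	anaplerosis	ME2	MAL (abcd) -> PYR.m (abc) + CO2 (d)	1.82E+02	1.81E+02	1.82E+02
NET	anaplerosis	ME1	MAL (abcd) -> PYR.c (abc) + CO2 (d)	5.91E-05	0.00E+00	8.06E-02
NET	anaplerosis	FAO	FAO.src (ab) -> AcCoA.m (ab)	1.15E-04	0.00E+00	1.56E-01
NET	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	1.59E+02	1.59E+02	1.59E+02
NET	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	1.74E+02	1.74E+02	1.74E+02
NET	tca	PDH	PYR.m (abc) -> AcCoA.m (bc) + CO2 (a)	2.55E+02	2.55E+02	2.55E+02
NET	tca	CS	AcCoA.m (ef) + OAC (abcd) -> CIT (dcbfea)	2.55E+02	2.55E+02	2.55E+02
NET	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	2.16E+01	2.16E+01	2.16E+01
NET	tca	OGDH	AKG (abcde) -> SUC (bcde) + CO2 (a)	1.81E+02	1.80E+02	1.81E+02
NET	tca	SDH	SUC (abcd) <-> FUM (abcd)	1.81E+02	1.80E+02	1.81E+02
NET	tca	FH	FUM (abcd) <-> MAL (abcd)	1.81E+02	1.80E+02	1.81E+02
NET	tca	MDH	MAL (abcd) <-> OAC (abcd)	2.32E+02	2.32E+02	2.33E+02
NET	tca	GOT	OAC (abcd) <-> ASP (abcd)	1.07E+01	1.06E+01	1.07E+01
NET	amino	PST	3PG (abc) -> SER (abc)	7.12E-01	7.01E-01	7.21E-01
NET	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	3.82E+00	3.81E+00	3.86E+00
NET	amino	CYST	SER (abc) <-> CYS (abc)	-6.35E+00	-6.35E+00	-6.35E+00
NET	amino	SD	SER (abc) -> PYR.c (abc)	2.33E+00	2.33E+00	2.33E+00
NET	amino	GLYS	CO2 (a) + MEETHF (b) -> GLY (ab)	1.80E+00	1.79E+00	1.81E+00
NET	biomass	BIOMASS	978*AcCoA.c + 237.8*ALA + 187*ASP + 92.3*CO2 + 57.46*CYS + 45.97*DHAP + 114.5*G6P + 127.6*GLN + 153*GLU + 260.8*GLY + 101.1*MEETHF + 92.3*P5P + 174.8*SER -> biomass	2.00E-02	2.00E-02	2.00E-02
NET	biomass	ACL	CIT (abcdef) -> AcCoA.c (ed) + MAL (fcba)	2.33E+02	2.33E+02	2.33E+02
NET	biomass	LIPS	AcCoA.c (ab) -> lipid (ab)	2.14E+02	2.14E+02	2.14E+02
NET	mixing	cPYR	0*PYR.c (abc) -> PYR.ms (abc)	1.00E+00	9.96E-01	1.00E+00
NET	mixing	mPYR	0*PYR.m (abc) -> PYR.ms (abc)	1.00E-07	0.00E+00	4.40E-03
NET	mixing	sPYR	PYR.ms (abc) -> PYR.fix (abc)	1.00E+00	1.00E+00	1.00E+00
EXCH	transport	MCT	LAC (abc) <-> LAC.x (abc)	1.64E+03	1.63E+03	1.65E+03
EXCH	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	5.69E-05	0.00E+00	1.71E-02
EXCH	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	9.92E+06	9.85E+04	Inf
EXCH	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	2.57E+02	2.56E+02	2.57E+02
EXCH	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	1.65E+03	1.63E+03	1.68E+03
EXCH	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	1.00E-07	0.00E+00	2.27E-01
EXCH	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	4.49E+02	4.49E+02	4.49E+02
EXCH	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	1.00E-07	0.00E+00	4.28E-02
EXCH	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	9.64E+01	0.00E+00	1.01E+02
EXCH	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	3.54E+01	3.54E+01	3.55E+01
EXCH	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	2.55E+00	2.54E+00	2.57E+00
EXCH	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	1.29E+01	1.29E+01	1.29E+01
EXCH	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	1.23E+03	1.23E+03	1.23E+03
EXCH	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	1.12E+00	1.07E+00	1.74E+00
EXCH	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	6.30E+01	6.30E+01	6.31E+01
EXCH	tca	SDH	SUC (abcd) <-> FUM (abcd)	3.34E+06	3.34E+06	3.34E+06
EXCH	tca	FH	FUM (abcd) <-> MAL (abcd)	2.18E+02	2.18E+02	2.18E+02
EXCH	tca	MDH	MAL (abcd) <-> OAC (abcd)	3.67E+03	3.67E+03	3.69E+03
EXCH	tca	GOT	OAC (abcd) <-> ASP (abcd)	1.54E+01	1.54E+01	1.55E+01
EXCH	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	1.60E-01	1.36E-01	1.70E-01
EXCH	amino	CYST	SER (abc) <-> CYS (abc)	2.00E-03	0.00E+00	2.00E-03
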