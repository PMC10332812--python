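type	pathway	id	reaction	flux	lb	ub
NET	transport	GLUT	GLC.x (abcdef) -> GLC (abcdef)	4.28E+02	4.28E+02	4.28E+02
NET	transport	PYRR	PYR.x (abc) -> PYR.c (abc)	1.04E+02	1.02E+02	1.09E+02
NET	transport	MCT	LAC (abc) <-> LAC.x (abc)	8.01E+02	8.01E+02	8.04E+02
NET	transport	ALAR	ALA (abc) -> ALA.x (abc)	1.43E+01	1.43E+01	1.46E+01
NET	transport	GLNR	GLN.x (abcde) -> GLN (abcde)	7.73E+01	7.53E+01	7.73E+01
NET	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	2.53E+01	2.52E+01	2.54E+01
NET	transport	ASPR	ASP (abcd) -> ASP.x (abcd)	7.01E+00	6.99E+00	7.02E+00
NET	transport	SERR	SER.x (abc) -> SER (abc)	2.54E+00	2.48E+00	2.55E+00
NET	transport	CYSR	CYX.x (abcdef) -> CYS (abc) + CYS (def)	6.39E+00	6.34E+00	6.45E+00
NET	transport	GLYR	GLY (ab) -> GLY.x (ab)	3.66E-01	3.03E-01	4.19E-01
NET	glycolysis	HK	GLC (abcdef) -> G6P (abcdef)	4.28E+02	4.28E+02	4.28E+02
NET	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	4.06E+02	4.06E+02	4.07E+02
NET	glycolysis	PFK	F6P (abcdef) -> FBP (abcdef)	4.17E+02	4.17E+02	4.18E+02
NET	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	4.17E+02	4.17E+02	4.18E+02
NET	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	4.16E+02	4.16E+02	4.16E+02
NET	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	8.39E+02	8.39E+02	8.41E+02
NET	glycolysis	ENO	3PG (abc) -> PEP (abc)	8.36E+02	8.35E+02	8.53E+02
NET	glycolysis	PK	PEP (abc) -> PYR.c (abc)	9.31E+02	9.30E+02	9.31E+02
NET	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	8.01E+02	8.01E+02	8.04E+02
NET	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	1.64E+02	1.62E+02	1.92E+02
NET	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	-1.43E+02	-1.43E+02	-1.42E+02
NET	ppp	G6PD	G6P (abcdef) -> P5P (bcdef) + CO2 (a)	1.89E+01	1.57E+01	1.93E+01
NET	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	5.46E+00	4.44E+00	5.96E+00
NET	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	5.46E+00	4.44E+00	5.96E+00
NET	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	5.46E+00	4.44E+00	5.96E+00
NET	anaplerosis	PYRT	PYR.c (abc) -> PYR.m (abc)	7.60E+01	7.59E+01	7.66E+01
NET	anaplerosis	PC	PYR.m (abc) + CO2 (d) -> OAC (abcd)	6.30E+01	6.29E+01	6.59E+01
NET	anaplerosis	PEPCK	OAC (abcd) -> PEP (abc) + CO2 (d)	9.51E+01	9.51E+01	9.53E+01
NET	anaplerosis	ME2	MAL (abcd) -> PYR.m (abc) + CO2 (d)	1.20E-03	0.00E+00	5.20E-03
NET	anaplerosis	ME1	MAL (abcd) -> PYR.c (abc) + CO2 (d)	3.29E-05	0.00E+00	1.15E+00
NET	anaplerosis	FAO	FAO.src (ab) -> AcCoA.m (ab)	1.00E-07	0.00E+00	1.32E-02
NET	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	4.43E+01	4.42E+01	4.45E+01
NET	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	7.38E+01	7.36E+01	7.38E+01
NET	tca	PDH	PYR.m (abc) -> AcCoA.m (bc) + CO2 (a)	1.56E+02	1.48E+02	1.66E+02
NET	tca	CS	AcCoA.m (ef) + OAC (abcd) -> CIT (dcbfea)	1.56E+02	1.56E+02	1.58E+02
NET	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	2.11E+01	2.10E+01	2.11E+01
NET	tca	OGDH	AKG (abcde) -> SUC (bcde) + CO2 (a)	6.54E+01	6.51E+01	6.59E+01
NET	tca	SDH	SUC (abcd) <-> FUM (abcd)	6.54E+01	6.51E+01	6.59E+01
NET	tca	FH	FUM (abcd) <-> MAL (abcd)	6.54E+01	6.51E+01	6.59E+01
NET	tca	MDH	MAL (abcd) <-> OAC (abcd)	2.01E+02	2.01E+02	2.01E+02
NET	tca	GOT	OAC (abcd) <-> ASP (abcd)	1.22E+01	1.17E+01	1.24E+01
NET	amino	PST	3PG (abc) -> SER (abc)	2.69E+00	2.57E+00	2.80E+00
NET	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	5.19E+00	5.15E+00	5.20E+00
NET	amino	CYST	SER (abc) <-> CYS (abc)	-1.12E+01	-1.17E+01	-1.11E+01
NET	amino	SD	SER (abc) -> PYR.c (abc)	6.39E+00	6.23E+00	6.44E+00
NET	amino	GLYS	CO2 (a) + MEETHF (b) -> GLY (ab)	2.39E+00	2.36E+00	2.42E+00
NET	biomass	BIOMASS	978*AcCoA.c + 237.8*ALA + 187*ASP + 92.3*CO2 + 57.46*CYS + 45.97*DHAP + 114.5*G6P + 127.6*GLN + 153*GLU + 260.8*GLY + 101.1*MEETHF + 92.3*P5P + 174.8*SER -> biomass	2.77E-02	2.70E-02	2.79E-02
NET	biomass	ACL	CIT (abcdef) -> AcCoA.c (ed) + MAL (fcba)	1.35E+02	1.34E+02	1.38E+02
NET	biomass	LIPS	AcCoA.c (ab) -> lipid (ab)	1.08E+02	9.99E+01	1.08E+02
NET	mixing	cPYR	0*PYR.c (abc) -> PYR.ms (abc)	5.77E-01	5.64E-01	5.92E-01
NET	mixing	mPYR	0*PYR.m (abc) -> PYR.ms (abc)	4.23E-01	4.08E-01	4.36E-01
NET	mixing	sPYR	PYR.ms (abc) -> PYR.fix (abc)	1.00E+00	1.00E+00	1.00E+00
EXCH	transport	MCT	LAC (abc) <-> LAC.x (abc)	1.00E-07	0.00E+00	1.36E+02
EXCH	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	1.00E-07	0.00E+00	2.27E-02
EXCH	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	4.88E+06	4.88E+06	Inf
EXCH	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	2.89E+02	2.80E+02	2.89E+02
EXCH	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	9.86E+06	-Inf	Inf
EXCH	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	1.12E+03	0.00E+00	5.88E+05
EXCH	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	1.47E+03	1.39E+03	1.47E+03
EXCH	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	2.74E+02	2.73E+02	2.77E+02
EXCH	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	1.38E+02	1.38E+02	1.49E+02
EXCH	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	7.99E+02	7.97E+02	8.08E+02
EXCH	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	1.53E-01	0.00E+00	5.82E-01
EXCH	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	3.33E+00	2.62E+00	3.35E+00
EXCH	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	5.36E+02	5.34E+02	8.37E+02
EXCH	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	3.20E-01	0.00E+00	2.74E+00
EXCH	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	1.04E+01	1.02E+01	1.04E+01
EXCH	tca	SDH	SUC (abcd) <-> FUM (abcd)	2.78E-01	0.00E+00	Inf
EXCH	tca	FH	FUM (abcd) <-> MAL (abcd)	1.03E-04	0.00E+00	1.58E+01
EXCH	tca	MDH	MAL (abcd) <-> OAC (abcd)	1.01E+03	8.27E+02	1.01E+03
EXCH	tca	GOT	OAC (abcd) <-> ASP (abcd)	2.27E+02	2.27E+02	2.47E+02
EXCH	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	3.55E+00	3.52E+00	3.59E+00
EXCH	amino	CYST	SER (abc) <-> CYS (abc)	1.04E+03	1.03E+03	1.04E+03
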