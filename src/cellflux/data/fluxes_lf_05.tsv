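type	pathway	id	reaction	flux	lb	ub
NET	transport	GLUT	GLC.x (abcdef) -> GLC (abcdef)	4.41E+02	4.26E+02	4.58E+02
NET	transport	PYRR	PYR.x (abc) -> PYR.c (abc)	6.21E+01	5.83E+01	6.60E+01
NET	transport	MCT	LAC (abc) <-> LAC.x (abc)	8.91E+02	8.62E+02	9.25E+02
NET	transport	ALAR	ALA (abc) -> ALA.x (abc)	5.84E-01	1.10E-03	1.16E+00
NET	transport	GLNR	GLN.x (abcde) -> GLN (abcde)	1.43E+01	1.26E+01	1.94E+01
NET	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	7.55E+00	6.88E+00	8.15E+00
NET	transport	ASPR	ASP (abcd) -> ASP.x (abcd)	1.08E+00	4.17E-01	1.69E+00
NET	transport	SERR	SER.x (abc) -> SER (abc)	5.49E+00	4.99E+00	6.06E+00
NET	transport	CYSR	CYX.x (abcdef) -> CYS (abc) + CYS (def)	1.65E+00	1.32E+00	2.08E+00
NET	transport	GLYR	GLY (ab) -> GLY.x (ab)	2.60E-01	2.00E-02	4.92E-01
NET	glycolysis	HK	GLC (abcdef) -> G6P (abcdef)	4.41E+02	4.26E+02	4.58E+02
NET	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	4.23E+02	4.04E+02	4.40E+02
NET	glycolysis	PFK	F6P (abcdef) -> FBP (abcdef)	4.32E+02	4.17E+02	4.49E+02
NET	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	4.32E+02	4.17E+02	4.49E+02
NET	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	4.31E+02	4.15E+02	4.48E+02
NET	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	8.69E+02	8.35E+02	9.03E+02
NET	glycolysis	ENO	3PG (abc) -> PEP (abc)	8.68E+02	8.36E+02	9.00E+02
NET	glycolysis	PK	PEP (abc) -> PYR.c (abc)	8.78E+02	8.36E+02	9.21E+02
NET	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	8.91E+02	8.62E+02	9.25E+02
NET	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	5.55E+00	-9.08E+02	6.13E+00
NET	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	-2.40E-03	-3.22E+01	9.11E+02
NET	ppp	G6PD	G6P (abcdef) -> P5P (bcdef) + CO2 (a)	1.62E+01	4.41E+00	2.89E+01
NET	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	4.76E+00	-1.22E-01	9.62E+00
NET	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	4.76E+00	-1.22E-01	9.62E+00
NET	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	4.76E+00	-1.22E-01	9.62E+00
NET	anaplerosis	PYRT	PYR.c (abc) -> PYR.m (abc)	4.42E+01	3.82E+01	9.58E+02
NET	anaplerosis	PC	PYR.m (abc) + CO2 (d) -> OAC (abcd)	1.37E+01	9.82E+00	2.69E+01
NET	anaplerosis	PEPCK	OAC (abcd) -> PEP (abc) + CO2 (d)	9.66E+00	0.00E+00	2.60E+01
NET	anaplerosis	ME2	MAL (abcd) -> PYR.m (abc) + CO2 (d)	1.00E-07	0.00E+00	2.25E+01
NET	anaplerosis	ME1	MAL (abcd) -> PYR.c (abc) + CO2 (d)	8.71E-05	0.00E+00	2.52E+01
NET	anaplerosis	FAO	FAO.src (ab) -> AcCoA.m (ab)	6.58E-06	0.00E+00	7.73E-01
NET	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	9.11E-01	-6.16E-01	7.27E+00
NET	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	1.17E+01	1.01E+01	1.70E+01
NET	tca	PDH	PYR.m (abc) -> AcCoA.m (bc) + CO2 (a)	3.05E+01	2.86E+01	5.24E+01
NET	tca	CS	AcCoA.m (ef) + OAC (abcd) -> CIT (dcbfea)	3.05E+01	2.88E+01	5.09E+01
NET	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	1.01E+01	8.75E+00	1.41E+01
NET	tca	OGDH	AKG (abcde) -> SUC (bcde) + CO2 (a)	1.10E+01	7.87E+00	2.02E+01
NET	tca	SDH	SUC (abcd) <-> FUM (abcd)	1.10E+01	7.87E+00	2.02E+01
NET	tca	FH	FUM (abcd) <-> MAL (abcd)	1.10E+01	7.87E+00	2.02E+01
NET	tca	MDH	MAL (abcd) <-> OAC (abcd)	3.14E+01	2.62E+01	5.70E+01
NET	tca	GOT	OAC (abcd) <-> ASP (abcd)	4.98E+00	4.32E+00	5.64E+00
NET	amino	PST	3PG (abc) -> SER (abc)	2.42E-01	1.34E-01	3.57E+01
NET	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	3.91E+00	3.71E+00	4.10E+00
NET	amino	CYST	SER (abc) <-> CYS (abc)	-2.10E+00	-2.97E+00	-1.44E+00
NET	amino	SD	SER (abc) -> PYR.c (abc)	2.82E-01	0.00E+00	1.47E+00
NET	amino	GLYS	CO2 (a) + MEETHF (b) -> GLY (ab)	1.80E+00	1.66E+00	1.93E+00
NET	biomass	BIOMASS	1216*AcCoA.c + 295.6*ALA + 232.4*ASP + 114.7*CO2 + 71.43*CYS + 57.14*DHAP + 142.4*G6P + 158.6*GLN + 190.1*GLU + 324.2*GLY + 125.6*MEETHF + 114.7*P5P + 217.2*SER -> biomass	1.68E-02	1.61E-02	1.75E-02
NET	biomass	ACL	CIT (abcdef) -> AcCoA.c (ed) + MAL (fcba)	2.04E+01	1.95E+01	3.71E+01
NET	biomass	LIPS	AcCoA.c (ab) -> lipid (ab)	1.00E-07	0.00E+00	1.68E+01
NET	mixing	cPYR	0*PYR.c (abc) -> PYR.ms (abc)	1.42E-01	0.00E+00	1.00E+00
NET	mixing	mPYR	0*PYR.m (abc) -> PYR.ms (abc)	8.58E-01	0.00E+00	1.00E+00
NET	mixing	sPYR	PYR.ms (abc) -> PYR.fix (abc)	1.00E+00	1.00E+00	1.00E+00
EXCH	transport	MCT	LAC (abc) <-> LAC.x (abc)	1.52E+03	1.35E+03	2.41E+03
EXCH	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	1.54E+00	1.11E+00	2.54E+00
EXCH	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	2.46E+05	0.00E+00	Inf
EXCH	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	3.20E+02	2.79E+02	3.60E+02
EXCH	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	1.70E+03	1.06E+03	3.06E+03
EXCH	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	1.00E-07	0.00E+00	2.39E+02
EXCH	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	4.80E+00	0.00E+00	3.51E+02
EXCH	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	8.32E+02	0.00E+00	9.06E+02
EXCH	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	1.28E-04	0.00E+00	
EXCH	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	1.47E+02	6.67E+01	2.60E+02
EXCH	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	2.35E-04	0.00E+00	7.54E+00
EXCH	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	9.05E+00	4.10E+00	1.43E+01
EXCH	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	3.78E+02	1.93E+02	1.94E+03
EXCH	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	1.00E-07	0.00E+00	3.84E-01
EXCH	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	2.52E+00	1.80E+00	4.50E+00
EXCH	tca	SDH	SUC (abcd) <-> FUM (abcd)	7.60E+01	2.57E+01	Inf
EXCH	tca	FH	FUM (abcd) <-> MAL (abcd)	5.05E+05	3.06E+02	Inf
EXCH	tca	MDH	MAL (abcd) <-> OAC (abcd)	1.33E+02	7.22E+01	3.25E+02
EXCH	tca	GOT	OAC (abcd) <-> ASP (abcd)	4.42E+01	0.00E+00	Inf
EXCH	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	6.07E-07	0.00E+00	3.32E+02
EXCH	amino	CYST	SER (abc) <-> CYS (abc)	1.46E-02	0.00E+00	Inf
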