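type	pathway	id	reaction	flux	lb	ub
NET	transport	GLUT	GLC.x (abcdef) -> GLC (abcdef)	6.12E+02	6.12E+02	6.12E+02
NET	transport	PYRR	PYR.x (abc) -> PYR.c (abc)	9.98E+01	9.95E+01	1.01E+02
NET	transport	MCT	LAC (abc) <-> LAC.x (abc)	8.19E+02	8.17E+02	8.20E+02
NET	transport	ALAR	ALA (abc) -> ALA.x (abc)	2.67E+00	2.36E+00	3.29E+00
NET	transport	GLNR	GLN.x (abcde) -> GLN (abcde)	3.78E+01	3.77E+01	3.79E+01
NET	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	1.61E+01	1.56E+01	1.62E+01
NET	transport	ASPR	ASP (abcd) -> ASP.x (abcd)	2.36E+00	2.32E+00	2.49E+00
NET	transport	SERR	SER.x (abc) -> SER (abc)	1.03E+01	1.03E+01	1.06E+01
NET	transport	CYSR	CYX.x (abcdef) -> CYS (abc) + CYS (def)	2.79E+00	2.79E+00	2.95E+00
NET	transport	GLYR	GLY (ab) -> GLY.x (ab)	2.52E+00	2.30E+00	2.73E+00
NET	glycolysis	HK	GLC (abcdef) -> G6P (abcdef)	6.12E+02	6.12E+02	6.12E+02
NET	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	6.09E+02	6.08E+02	6.09E+02
NET	glycolysis	PFK	F6P (abcdef) -> FBP (abcdef)	6.07E+02	6.07E+02	6.07E+02
NET	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	6.07E+02	6.07E+02	6.07E+02
NET	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	6.06E+02	6.06E+02	6.06E+02
NET	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	1.21E+03	1.21E+03	1.21E+03
NET	glycolysis	ENO	3PG (abc) -> PEP (abc)	1.21E+03	1.21E+03	1.21E+03
NET	glycolysis	PK	PEP (abc) -> PYR.c (abc)	1.23E+03	1.19E+03	1.23E+03
NET	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	8.19E+02	8.17E+02	8.20E+02
NET	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	9.62E+00	9.44E+00	9.62E+00
NET	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	1.14E-01		
NET	ppp	G6PD	G6P (abcdef) -> P5P (bcdef) + CO2 (a)	2.02E-02	0.00E+00	1.08E+00
NET	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	-9.06E-01	-9.28E-01	-9.06E-01
NET	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	-9.06E-01	-9.28E-01	-9.06E-01
NET	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	-9.06E-01	-9.28E-01	-9.06E-01
NET	anaplerosis	PYRT	PYR.c (abc) -> PYR.m (abc)	4.99E+02	4.97E+02	4.99E+02
NET	anaplerosis	PC	PYR.m (abc) + CO2 (d) -> OAC (abcd)	2.11E+01	2.07E+01	2.17E+01
NET	anaplerosis	PEPCK	OAC (abcd) -> PEP (abc) + CO2 (d)	1.36E+01	1.36E+01	1.37E+01
NET	anaplerosis	ME2	MAL (abcd) -> PYR.m (abc) + CO2 (d)	1.30E+01	1.28E+01	1.37E+01
NET	anaplerosis	ME1	MAL (abcd) -> PYR.c (abc) + CO2 (d)	3.20E-03	0.00E+00	1.73E+00
NET	anaplerosis	FAO	FAO.src (ab) -> AcCoA.m (ab)	1.00E-07	0.00E+00	3.48E+00
NET	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	1.33E+01	1.31E+01	1.35E+01
NET	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	3.40E+01	3.35E+01	3.42E+01
NET	tca	PDH	PYR.m (abc) -> AcCoA.m (bc) + CO2 (a)	4.90E+02	4.90E+02	4.92E+02
NET	tca	CS	AcCoA.m (ef) + OAC (abcd) -> CIT (dcbfea)	4.90E+02	4.84E+02	4.91E+02
NET	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	2.70E+01	2.70E+01	2.76E+01
NET	tca	OGDH	AKG (abcde) -> SUC (bcde) + CO2 (a)	4.03E+01	3.99E+01	4.04E+01
NET	tca	SDH	SUC (abcd) <-> FUM (abcd)	4.03E+01	3.99E+01	4.04E+01
NET	tca	FH	FUM (abcd) <-> MAL (abcd)	4.03E+01	3.99E+01	4.04E+01
NET	tca	MDH	MAL (abcd) <-> OAC (abcd)	4.91E+02	4.91E+02	4.92E+02
NET	tca	GOT	OAC (abcd) <-> ASP (abcd)	7.91E+00	7.76E+00	7.98E+00
NET	amino	PST	3PG (abc) -> SER (abc)	4.03E-01	3.74E-01	5.04E-01
NET	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	6.63E+00	6.59E+00	6.65E+00
NET	amino	CYST	SER (abc) <-> CYS (abc)	-3.88E+00	-3.91E+00	-3.87E+00
NET	amino	SD	SER (abc) -> PYR.c (abc)	2.80E+00	2.80E+00	2.80E+00
NET	amino	GLYS	CO2 (a) + MEETHF (b) -> GLY (ab)	3.63E+00	3.50E+00	3.65E+00
NET	biomass	BIOMASS	1216*AcCoA.c + 295.6*ALA + 232.4*ASP + 114.7*CO2 + 71.43*CYS + 57.14*DHAP + 142.4*G6P + 158.6*GLN + 190.1*GLU + 324.2*GLY + 125.6*MEETHF + 114.7*P5P + 217.2*SER -> biomass	2.39E-02	2.39E-02	2.50E-02
NET	biomass	ACL	CIT (abcdef) -> AcCoA.c (ed) + MAL (fcba)	4.63E+02	4.63E+02	4.66E+02
NET	biomass	LIPS	AcCoA.c (ab) -> lipid (ab)	4.34E+02	4.29E+02	4.34E+02
NET	mixing	cPYR	0*PYR.c (abc) -> PYR.ms (abc)	1.00E+00	9.99E-01	1.00E+00
NET	mixing	mPYR	0*PYR.m (abc) -> PYR.ms (abc)	1.00E-07	0.00E+00	9.83E-04
NET	mixing	sPYR	PYR.ms (abc) -> PYR.fix (abc)	1.00E+00	1.00E+00	1.00E+00
EXCH	transport	MCT	LAC (abc) <-> LAC.x (abc)	6.24E-04	0.00E+00	3.56E+00
EXCH	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	5.06E+00	4.82E+00	5.75E+00
EXCH	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	1.40E+06	1.39E+06	Inf
EXCH	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	2.38E+02	2.38E+02	2.38E+02
EXCH	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	9.99E+06		Inf
EXCH	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	5.81E+02	5.81E+02	7.25E+02
EXCH	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	2.65E+03	2.58E+03	2.65E+03
EXCH	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	1.00E-07	0.00E+00	5.60E-02
EXCH	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	1.00E-07	0.00E+00	5.65E-02
EXCH	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	1.28E+06	9.01E+03	Inf
EXCH	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	8.89E+00	8.88E+00	9.53E+00
EXCH	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	6.93E+00	5.12E+00	6.98E+00
EXCH	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	5.63E+03	4.43E+03	5.66E+03
EXCH	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	1.27E+00	1.20E+00	1.50E+00
EXCH	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	3.36E+00	3.24E+00	3.92E+00
EXCH	tca	SDH	SUC (abcd) <-> FUM (abcd)	4.30E+02	4.30E+02	1.46E+06
EXCH	tca	FH	FUM (abcd) <-> MAL (abcd)	7.29E+06	-Inf	Inf
EXCH	tca	MDH	MAL (abcd) <-> OAC (abcd)	5.49E+02	5.47E+02	5.49E+02
EXCH	tca	GOT	OAC (abcd) <-> ASP (abcd)	1.04E+02	1.04E+02	1.04E+02
EXCH	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	1.39E+00	1.37E+00	1.41E+00
EXCH	amino	CYST	SER (abc) <-> CYS (abc)	1.25E-07	0.00E+00	4.22E-02
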