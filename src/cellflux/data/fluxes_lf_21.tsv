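type	pathway	id	reaction	flux	lb	ub
NET	transport	GLUT	GLC.x (abcdef) -> GLC (abcdef)	5.14E+02	5.11E+02	5.21E+02
NET	transport	PYRR	PYR.x (abc) -> PYR.c (abc)	7.56E+01	7.31E+01	7.96E+01
NET	transport	MCT	LAC (abc) <-> LAC.x (abc)	9.99E+02	9.98E+02	1.02E+03
NET	transport	ALAR	ALA (abc) -> ALA.x (abc)	2.25E+00	1.95E+00	2.49E+00
NET	transport	GLNR	GLN.x (abcde) -> GLN (abcde)	4.15E+01	4.06E+01	4.16E+01
NET	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	1.62E+01	1.58E+01	1.68E+01
NET	transport	ASPR	ASP (abcd) -> ASP.x (abcd)	2.57E+00	2.53E+00	2.68E+00
NET	transport	SERR	SER.x (abc) -> SER (abc)	1.42E+01	1.35E+01	1.49E+01
NET	transport	CYSR	CYX.x (abcdef) -> CYS (abc) + CYS (def)	4.41E+00	4.23E+00	4.58E+00
NET	transport	GLYR	GLY (ab) -> GLY.x (ab)	2.05E+00	1.90E+00	2.15E+00
NET	glycolysis	HK	GLC (abcdef) -> G6P (abcdef)	5.14E+02	5.11E+02	5.21E+02
NET	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	5.11E+02	4.99E+02	5.24E+02
NET	glycolysis	PFK	F6P (abcdef) -> FBP (abcdef)	5.09E+02	5.00E+02	5.12E+02
NET	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	5.09E+02	5.00E+02	5.12E+02
NET	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	5.08E+02	5.06E+02	5.08E+02
NET	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	1.02E+03	9.96E+02	1.04E+03
NET	glycolysis	ENO	3PG (abc) -> PEP (abc)	1.01E+03	9.99E+02	1.03E+03
NET	glycolysis	PK	PEP (abc) -> PYR.c (abc)	1.04E+03	9.95E+02	1.04E+03
NET	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	9.99E+02	9.98E+02	1.02E+03
NET	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	1.19E+01	9.12E+00	1.19E+01
NET	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	-2.58E+00	-4.56E+00	2.87E+00
NET	ppp	G6PD	G6P (abcdef) -> P5P (bcdef) + CO2 (a)	1.26E-07	0.00E+00	3.91E-01
NET	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	-9.11E-01	-9.29E-01	-8.30E-01
NET	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	-9.11E-01	-9.29E-01	-8.30E-01
NET	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	-9.11E-01	-9.29E-01	-8.30E-01
NET	anaplerosis	PYRT	PYR.c (abc) -> PYR.m (abc)	1.16E+02	1.16E+02	1.19E+02
NET	anaplerosis	PC	PYR.m (abc) + CO2 (d) -> OAC (abcd)	1.88E+01	1.74E+01	1.91E+01
NET	anaplerosis	PEPCK	OAC (abcd) -> PEP (abc) + CO2 (d)	2.56E+01	1.58E+01	2.57E+01
NET	anaplerosis	ME2	MAL (abcd) -> PYR.m (abc) + CO2 (d)	2.05E+00	9.51E-02	2.68E+00
NET	anaplerosis	ME1	MAL (abcd) -> PYR.c (abc) + CO2 (d)	2.78E-02	0.00E+00	2.63E+01
NET	anaplerosis	FAO	FAO.src (ab) -> AcCoA.m (ab)	1.00E-07	0.00E+00	2.13E+00
NET	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	1.71E+01	1.56E+01	1.84E+01
NET	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	3.78E+01	3.60E+01	3.86E+01
NET	tca	PDH	PYR.m (abc) -> AcCoA.m (bc) + CO2 (a)	1.02E+02	8.76E+01	1.15E+02
NET	tca	CS	AcCoA.m (ef) + OAC (abcd) -> CIT (dcbfea)	1.02E+02	8.30E+01	1.11E+02
NET	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	2.49E+01	2.42E+01	2.53E+01
NET	tca	OGDH	AKG (abcde) -> SUC (bcde) + CO2 (a)	4.19E+01	4.01E+01	4.25E+01
NET	tca	SDH	SUC (abcd) <-> FUM (abcd)	4.19E+01	4.01E+01	4.25E+01
NET	tca	FH	FUM (abcd) <-> MAL (abcd)	4.19E+01	4.01E+01	4.25E+01
NET	tca	MDH	MAL (abcd) <-> OAC (abcd)	1.17E+02	1.08E+02	1.24E+02
NET	tca	GOT	OAC (abcd) <-> ASP (abcd)	8.11E+00	8.06E+00	8.23E+00
NET	amino	PST	3PG (abc) -> SER (abc)	1.95E+00	1.63E+00	2.00E+00
NET	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	6.38E+00	6.22E+00	6.43E+00
NET	amino	CYST	SER (abc) <-> CYS (abc)	-7.12E+00	-7.19E+00	-6.81E+00
NET	amino	SD	SER (abc) -> PYR.c (abc)	1.17E+01	1.04E+01	1.20E+01
NET	amino	GLYS	CO2 (a) + MEETHF (b) -> GLY (ab)	3.39E+00	3.35E+00	3.49E+00
NET	biomass	BIOMASS	1216*AcCoA.c + 295.6*ALA + 232.4*ASP + 114.7*CO2 + 71.43*CYS + 57.14*DHAP + 142.4*G6P + 158.6*GLN + 190.1*GLU + 324.2*GLY + 125.6*MEETHF + 114.7*P5P + 217.2*SER -> biomass	2.38E-02	2.34E-02	2.39E-02
NET	biomass	ACL	CIT (abcdef) -> AcCoA.c (ed) + MAL (fcba)	7.74E+01	6.29E+01	1.04E+02
NET	biomass	LIPS	AcCoA.c (ab) -> lipid (ab)	4.84E+01	4.55E+01	4.84E+01
NET	mixing	cPYR	0*PYR.c (abc) -> PYR.ms (abc)	1.00E+00	8.47E-01	1.00E+00
NET	mixing	mPYR	0*PYR.m (abc) -> PYR.ms (abc)	1.00E-07	0.00E+00	1.53E-01
NET	mixing	sPYR	PYR.ms (abc) -> PYR.fix (abc)	1.00E+00	1.00E+00	1.00E+00
EXCH	transport	MCT	LAC (abc) <-> LAC.x (abc)	1.00E-07	0.00E+00	1.05E-01
EXCH	transport	GLUR	GLU (abcde) <-> GLU.x (abcde)	5.10E+00	4.77E+00	5.23E+00
EXCH	glycolysis	PGI	G6P (abcdef) <-> F6P (abcdef)	2.78E+05	1.77E+05	Inf
EXCH	glycolysis	ALDO	FBP (abcdef) <-> DHAP (cba) + GAP (def)	1.43E+02	1.43E+02	1.43E+02
EXCH	glycolysis	TPI	DHAP (abc) <-> GAP (abc)	4.33E+03	4.33E+03	1.09E+04
EXCH	glycolysis	GAPDH	GAP (abc) <-> 3PG (abc)	4.42E+02	4.72E+00	4.50E+02
EXCH	glycolysis	LDH	PYR.c (abc) <-> LAC (abc)	1.63E+03	1.62E+03	1.80E+03
EXCH	glycolysis	GPT1	PYR.c (abc) <-> ALA (abc)	1.00E-07	0.00E+00	2.61E-01
EXCH	glycolysis	GPT2	PYR.m (abc) <-> ALA (abc)	4.21E-04	0.00E+00	2.92E+00
EXCH	ppp	TK1	P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)	9.97E+04	6.27E+03	Inf
EXCH	ppp	TA	S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)	5.93E+00	5.79E+00	6.97E+00
EXCH	ppp	TK2	P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)	1.00E+07	-Inf	Inf
EXCH	anaplerosis	GLDH	GLU (abcde) <-> AKG (abcde)	1.52E+03	1.52E+03	7.13E+03
EXCH	anaplerosis	GLS	GLN (abcde) <-> GLU (abcde)	3.99E-01	0.00E+00	8.04E-01
EXCH	tca	IDH	CIT (abcdef) <-> AKG (abcde) + CO2 (f)	4.55E+00	4.03E+00	5.19E+00
EXCH	tca	SDH	SUC (abcd) <-> FUM (abcd)	1.22E+03		Inf
EXCH	tca	FH	FUM (abcd) <-> MAL (abcd)	3.66E+05	1.95E+05	Inf
EXCH	tca	MDH	MAL (abcd) <-> OAC (abcd)	1.11E+03	7.88E+02	2.38E+03
EXCH	tca	GOT	OAC (abcd) <-> ASP (abcd)	1.00E+07	-Inf	Inf
EXCH	amino	SHT	SER (abc) <-> GLY (ab) + MEETHF (c)	5.10E+00	8.92E-01	5.25E+00
EXCH	amino	CYST	SER (abc) <-> CYS (abc)	1.52E-05	0.00E+00	2.55E-04
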