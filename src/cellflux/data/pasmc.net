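# Central-carbon network for proliferating pulmonary artery smooth muscle cells: glycolysis,
# pentose phosphate pathway, TCA cycle, anaplerosis, serine metabolism and
# biomass synthesis.  48 reactions; seven extracellular substrates (ASP not
# consumed here: aspartate transport is efflux-only in this variant), five
# products (alanine, biomass, glutamate, lactate, lipid).
#
# Atom maps are reconstructed from standard biochemistry (published tables
# give the reactions but not per-carbon letters); CO2 is an unbalanced,
# unlabeled pool (decarboxylation CO2 leaves, carboxylation draws unlabeled
# CO2); FAO.src is an unlabeled acetyl-CoA source standing in for fatty-acid
# oxidation; PYR.ms is the measured-pyruvate mixing pool.

% unbalanced: GLC.x PYR.x LAC.x ALA.x GLN.x GLU.x ASP.x SER.x CYX.x GLY.x CO2 FAO.src biomass lipid PYR.ms PYR.fix
% symmetric: SUC FUM

# -- transport -------------------------------------------------------------
GLUT:  GLC.x (abcdef) -> GLC (abcdef)                     | pathway=transport
PYRR:  PYR.x (abc) -> PYR.c (abc)                         | pathway=transport
MCT:   LAC (abc) <-> LAC.x (abc)                          | pathway=transport
ALAR:  ALA (abc) -> ALA.x (abc)                           | pathway=transport
GLNR:  GLN.x (abcde) -> GLN (abcde)                       | pathway=transport
GLUR:  GLU (abcde) <-> GLU.x (abcde)                      | pathway=transport
ASPR:  ASP (abcd) -> ASP.x (abcd)                         | pathway=transport
SERR:  SER.x (abc) -> SER (abc)                           | pathway=transport
CYSR:  CYX.x (abcdef) -> CYS (abc) + CYS (def)            | pathway=transport
GLYR:  GLY (ab) -> GLY.x (ab)                             | pathway=transport

# -- glycolysis ------------------------------------------------------------
HK:    GLC (abcdef) -> G6P (abcdef)                       | pathway=glycolysis
PGI:   G6P (abcdef) <-> F6P (abcdef)                      | pathway=glycolysis
PFK:   F6P (abcdef) -> FBP (abcdef)                       | pathway=glycolysis
ALDO:  FBP (abcdef) <-> DHAP (cba) + GAP (def)            | pathway=glycolysis
TPI:   DHAP (abc) <-> GAP (abc)                           | pathway=glycolysis
GAPDH: GAP (abc) <-> 3PG (abc)                            | pathway=glycolysis
ENO:   3PG (abc) -> PEP (abc)                             | pathway=glycolysis
PK:    PEP (abc) -> PYR.c (abc)                           | pathway=glycolysis
LDH:   PYR.c (abc) <-> LAC (abc)                          | pathway=glycolysis
GPT1:  PYR.c (abc) <-> ALA (abc)                          | pathway=glycolysis
GPT2:  PYR.m (abc) <-> ALA (abc)                          | pathway=glycolysis

# -- pentose phosphate pathway ----------------------------------------------
G6PD:  G6P (abcdef) -> P5P (bcdef) + CO2 (a)              | pathway=ppp
TK1:   P5P (abcde) + P5P (fghij) <-> S7P (abfghij) + GAP (cde)  | pathway=ppp
TA:    S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg)  | pathway=ppp
TK2:   P5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde)    | pathway=ppp

# -- anaplerosis -------------------------------------------------------------
PYRT:  PYR.c (abc) -> PYR.m (abc)                         | pathway=anaplerosis
PC:    PYR.m (abc) + CO2 (d) -> OAC (abcd)                | pathway=anaplerosis
PEPCK: OAC (abcd) -> PEP (abc) + CO2 (d)                  | pathway=anaplerosis
ME2:   MAL (abcd) -> PYR.m (abc) + CO2 (d)                | pathway=anaplerosis
ME1:   MAL (abcd) -> PYR.c (abc) + CO2 (d)                | pathway=anaplerosis
FAO:   FAO.src (ab) -> AcCoA.m (ab)  | pathway=anaplerosis pseudo=source
GLDH:  GLU (abcde) <-> AKG (abcde)                        | pathway=anaplerosis
GLS:   GLN (abcde) <-> GLU (abcde)                        | pathway=anaplerosis

# -- tricarboxylic acid cycle -----------------------------------------------
PDH:   PYR.m (abc) -> AcCoA.m (bc) + CO2 (a)              | pathway=tca
CS:    AcCoA.m (ef) + OAC (abcd) -> CIT (dcbfea)          | pathway=tca
IDH:   CIT (abcdef) <-> AKG (abcde) + CO2 (f)             | pathway=tca
OGDH:  AKG (abcde) -> SUC (bcde) + CO2 (a)                | pathway=tca
SDH:   SUC (abcd) <-> FUM (abcd)                          | pathway=tca
FH:    FUM (abcd) <-> MAL (abcd)                          | pathway=tca
MDH:   MAL (abcd) <-> OAC (abcd)                          | pathway=tca
GOT:   OAC (abcd) <-> ASP (abcd)                          | pathway=tca

# -- serine / amino acid metabolism -------------------------------------------
PST:   3PG (abc) -> SER (abc)                             | pathway=amino
SHT:   SER (abc) <-> GLY (ab) + MEETHF (c)                | pathway=amino
CYST:  SER (abc) <-> CYS (abc)                            | pathway=amino
SD:    SER (abc) -> PYR.c (abc)                           | pathway=amino
GLYS:  CO2 (a) + MEETHF (b) -> GLY (ab)                   | pathway=amino

# -- biomass ------------------------------------------------------------------
BIOMASS: 978*AcCoA.c + 237.8*ALA + 187*ASP + 92.3*CO2 + 57.46*CYS + 45.97*DHAP + 114.5*G6P + 127.6*GLN + 153*GLU + 260.8*GLY + 101.1*MEETHF + 92.3*P5P + 174.8*SER -> biomass | pathway=biomass
ACL:   CIT (abcdef) -> AcCoA.c (ed) + MAL (fcba)          | pathway=biomass
LIPS:  AcCoA.c (ab) -> lipid (ab)                         | pathway=biomass

# -- measured-pyruvate mixing pool --------------------------------------------
cPYR:  0*PYR.c (abc) -> PYR.ms (abc)   | pathway=mixing pseudo=mixing
mPYR:  0*PYR.m (abc) -> PYR.ms (abc)   | pathway=mixing pseudo=mixing
sPYR:  PYR.ms (abc) -> PYR.fix (abc)   | pathway=mixing pseudo=mixing
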