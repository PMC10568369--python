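# Protein heavy-atom SYBYL typing for the 20 standard amino acids.
# Format: RES_NAME ATOM_NAME TYPE_ID   (see surfkit.atomtypes.SYBYL_TYPES)
ALA N 10
ALA CA 3
ALA C 2
ALA O 13
ALA OXT 15
ALA CB 3
ARG N 10
ARG CA 3
ARG C 2
ARG O 13
ARG OXT 15
ARG CB 3
ARG CG 3
ARG CD 3
ARG NE 12
ARG CZ 5
ARG NH1 12
ARG NH2 12
ASN N 10
ASN CA 3
ASN C 2
ASN O 13
ASN OXT 15
ASN CB 3
ASN CG 2
ASN OD1 13
ASN ND2 10
ASP N 10
ASP CA 3
ASP C 2
ASP O 13
ASP OXT 15
ASP CB 3
ASP CG 2
ASP OD1 15
ASP OD2 15
CYS N 10
CYS CA 3
CYS C 2
CYS O 13
CYS OXT 15
CYS CB 3
CYS SG 17
GLN N 10
GLN CA 3
GLN C 2
GLN O 13
GLN OXT 15
GLN CB 3
GLN CG 3
GLN CD 2
GLN OE1 13
GLN NE2 10
GLU N 10
GLU CA 3
GLU C 2
GLU O 13
GLU OXT 15
GLU CB 3
GLU CG 3
GLU CD 2
GLU OE1 15
GLU OE2 15
GLY N 10
GLY CA 3
GLY C 2
GLY O 13
GLY OXT 15
HIS N 10
HIS CA 3
HIS C 2
HIS O 13
HIS OXT 15
HIS CB 3
HIS CG 4
HIS ND1 11
HIS CD2 4
HIS CE1 4
HIS NE2 11
ILE N 10
ILE CA 3
ILE C 2
ILE O 13
ILE OXT 15
ILE CB 3
ILE CG1 3
ILE CG2 3
ILE CD1 3
LEU N 10
LEU CA 3
LEU C 2
LEU O 13
LEU OXT 15
LEU CB 3
LEU CG 3
LEU CD1 3
LEU CD2 3
LYS N 10
LYS CA 3
LYS C 2
LYS O 13
LYS OXT 15
LYS CB 3
LYS CG 3
LYS CD 3
LYS CE 3
LYS NZ 9
MET N 10
MET CA 3
MET C 2
MET O 13
MET OXT 15
MET CB 3
MET CG 3
MET SD 17
MET CE 3
PHE N 10
PHE CA 3
PHE C 2
PHE O 13
PHE OXT 15
PHE CB 3
PHE CG 4
PHE CD1 4
PHE CD2 4
PHE CE1 4
PHE CE2 4
PHE CZ 4
PRO N 10
PRO CA 3
PRO C 2
PRO O 13
PRO OXT 15
PRO CB 3
PRO CG 3
PRO CD 3
SER N 10
SER CA 3
SER C 2
SER O 13
SER OXT 15
SER CB 3
SER OG 14
THR N 10
THR CA 3
THR C 2
THR O 13
THR OXT 15
THR CB 3
THR OG1 14
THR CG2 3
TRP N 10
TRP CA 3
TRP C 2
TRP O 13
TRP OXT 15
TRP CB 3
TRP CG 4
TRP CD1 4
TRP CD2 4
TRP NE1 11
TRP CE2 4
TRP CE3 4
TRP CZ2 4
TRP CZ3 4
TRP CH2 4
TYR N 10
TYR CA 3
TYR C 2
TYR O 13
TYR OXT 15
TYR CB 3
TYR CG 4
TYR CD1 4
TYR CD2 4
TYR CE1 4
TYR CE2 4
TYR CZ 4
TYR OH 14
VAL N 10
VAL CA 3
VAL C 2
VAL O 13
VAL OXT 15
VAL CB 3
VAL CG1 3
VAL CG2 3
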