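# Standard Voronoi atomic volumes (Angstrom^3) by residue and atom name,
# assembled from ProtOr chemical-class mean volumes (united heavy atoms).
# Columns: resname atomname volume.  'element X v' rows are fallbacks
# (element-level medians) used, with a warning, for unmatched atom names.
ALA N    15.7
ALA CA   14.4
ALA C    9.7
ALA O    15.9
ALA OXT  18.0
ALA CB   36.7
ARG N    15.7
ARG CA   14.4
ARG C    9.7
ARG O    15.9
ARG OXT  18.0
ARG CB   23.2
ARG CG   23.2
ARG CD   23.2
ARG NE   15.7
ARG CZ   9.7
ARG NH1  22.7
ARG NH2  22.7
ASN N    15.7
ASN CA   14.4
ASN C    9.7
ASN O    15.9
ASN OXT  18.0
ASN CB   23.2
ASN CG   9.7
ASN OD1  15.9
ASN ND2  22.7
ASP N    15.7
ASP CA   14.4
ASP C    9.7
ASP O    15.9
ASP OXT  18.0
ASP CB   23.2
ASP CG   9.7
ASP OD1  15.9
ASP OD2  15.9
CYS N    15.7
CYS CA   14.4
CYS C    9.7
CYS O    15.9
CYS OXT  18.0
CYS CB   23.2
CYS SG   36.7
GLN N    15.7
GLN CA   14.4
GLN C    9.7
GLN O    15.9
GLN OXT  18.0
GLN CB   23.2
GLN CG   23.2
GLN CD   9.7
GLN OE1  15.9
GLN NE2  22.7
GLU N    15.7
GLU CA   14.4
GLU C    9.7
GLU O    15.9
GLU OXT  18.0
GLU CB   23.2
GLU CG   23.2
GLU CD   9.7
GLU OE1  15.9
GLU OE2  15.9
GLY N    15.7
GLY CA   23.2
GLY C    9.7
GLY O    15.9
GLY OXT  18.0
HIS N    15.7
HIS CA   14.4
HIS C    9.7
HIS O    15.9
HIS OXT  18.0
HIS CB   23.2
HIS CG   9.7
HIS ND1  15.7
HIS CD2  20.4
HIS CE1  20.4
HIS NE2  15.7
ILE N    15.7
ILE CA   14.4
ILE C    9.7
ILE O    15.9
ILE OXT  18.0
ILE CB   14.4
ILE CG1  23.2
ILE CG2  36.7
ILE CD1  36.7
LEU N    15.7
LEU CA   14.4
LEU C    9.7
LEU O    15.9
LEU OXT  18.0
LEU CB   23.2
LEU CG   14.4
LEU CD1  36.7
LEU CD2  36.7
LYS N    15.7
LYS CA   14.4
LYS C    9.7
LYS O    15.9
LYS OXT  18.0
LYS CB   23.2
LYS CG   23.2
LYS CD   23.2
LYS CE   23.2
LYS NZ   21.4
MET N    15.7
MET CA   14.4
MET C    9.7
MET O    15.9
MET OXT  18.0
MET CB   23.2
MET CG   23.2
MET SD   29.2
MET CE   36.7
PHE N    15.7
PHE CA   14.4
PHE C    9.7
PHE O    15.9
PHE OXT  18.0
PHE CB   23.2
PHE CG   9.7
PHE CD1  20.4
PHE CD2  20.4
PHE CE1  20.4
PHE CE2  20.4
PHE CZ   20.4
PRO N    8.7
PRO CA   14.4
PRO C    9.7
PRO O    15.9
PRO OXT  18.0
PRO CB   23.2
PRO CG   23.2
PRO CD   23.2
SER N    15.7
SER CA   14.4
SER C    9.7
SER O    15.9
SER OXT  18.0
SER CB   23.2
SER OG   18.0
THR N    15.7
THR CA   14.4
THR C    9.7
THR O    15.9
THR OXT  18.0
THR CB   14.4
THR OG1  18.0
THR CG2  36.7
TRP N    15.7
TRP CA   14.4
TRP C    9.7
TRP O    15.9
TRP OXT  18.0
TRP CB   23.2
TRP CG   9.7
TRP CD1  20.4
TRP CD2  9.7
TRP NE1  15.7
TRP CE2  9.7
TRP CE3  20.4
TRP CZ2  20.4
TRP CZ3  20.4
TRP CH2  20.4
TYR N    15.7
TYR CA   14.4
TYR C    9.7
TYR O    15.9
TYR OXT  18.0
TYR CB   23.2
TYR CG   9.7
TYR CD1  20.4
TYR CD2  20.4
TYR CE1  20.4
TYR CE2  20.4
TYR CZ   9.7
TYR OH   18.0
VAL N    15.7
VAL CA   14.4
VAL C    9.7
VAL O    15.9
VAL OXT  18.0
VAL CB   14.4
VAL CG1  36.7
VAL CG2  36.7
element C 14.4
element N 15.7
element O 15.9
element S 33.0
element SE 29.2
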