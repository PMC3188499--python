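# Coarse backbone-independent rotamer library.
# One rotamer per line: residue three-letter code followed by chi angles in
# degrees. Residues without rotatable chi angles (GLY, ALA, PRO) carry a
# single empty entry. Users may substitute their own file with the same
# layout via RotamerLibrary.from_file().
GLY
ALA
PRO
SER -65
SER 180
SER 65
CYS -65
CYS 180
CYS 65
THR -60
THR 60
THR 180
VAL 175
VAL -60
VAL 65
ILE -65 170
ILE -65 65
ILE -57 -60
ILE 62 170
ILE 180 170
ILE 180 65
LEU -65 175
LEU -70 65
LEU 180 60
LEU 180 180
LEU 65 175
MET -65 -65 -70
MET -65 -65 100
MET -65 180 75
MET -65 180 180
MET -65 180 -75
MET 180 180 75
MET 180 180 180
MET 180 180 -75
MET 180 65 75
MET 65 65 -75
ASP -70 -15
ASP -70 30
ASP 180 0
ASP 180 65
ASP 65 -10
ASN -65 -40
ASN -65 120
ASN 180 -80
ASN 180 30
ASN 65 -20
GLU -65 180 -10
GLU -65 -65 -40
GLU -65 85 0
GLU 180 180 0
GLU 180 65 10
GLU 65 180 0
GLN -65 180 -25
GLN -65 -65 -40
GLN -65 180 100
GLN 180 180 0
GLN 180 65 90
GLN 65 180 20
LYS -65 180 180 180
LYS -65 -65 180 180
LYS -65 180 -65 180
LYS 180 180 180 180
LYS 180 65 180 180
LYS 65 180 180 180
ARG -65 180 180 180
ARG -65 -65 180 180
ARG -65 180 -65 180
ARG 180 180 180 180
ARG 180 65 180 180
ARG 65 180 180 180
HIS -65 -70
HIS -65 90
HIS 180 -100
HIS 180 80
HIS 65 -75
PHE -65 90
PHE -65 -85
PHE 180 80
PHE 180 -80
PHE 65 90
TYR -65 90
TYR -65 -85
TYR 180 80
TYR 180 -80
TYR 65 90
TRP -65 95
TRP -65 -90
TRP 180 -105
TRP 180 75
TRP 65 -90
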