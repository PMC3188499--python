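sequence	label	score
CYLI	MTO	-3.96
CYLE	STO	-3.82
CYLV	MTO	-3.60
CFLV	MTO	-3.60
CLII	MTO	-3.51
CYVE	MTO	-3.43
CYIE	MTO	-3.40
CFIE	STO	-3.34
CLIV	MTO	-3.33
CYLL	MTO	-3.24
CYLD	MTO	-3.13
CWVI	STO	-3.03
CWLV	MTO	-3.01
CYVA	MTO	-2.88
CFLT	MTO	-2.74
CAFI	STO	-2.62
CWLS	MTO	-2.46
CCLS	MTO	-2.37
CTTE	STO	-2.14
CHFH	STO	-2.14
CKLA	MTO	-2.06
CWTC	MTO	-1.94
CSLI	MTO	-1.90
CLFE	NON	-1.77
CPFF	STO	-1.69
CGVG	MTO	-1.65
CFDI	NON	-1.59
CHCI	NON	-1.56
CVCV	MTO	-1.12
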