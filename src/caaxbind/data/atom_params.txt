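# Nonbonded atom-type parameters.
# type    radius(A)  eps    charge  gfree  vol(A^3)  donor  acceptor
# radius: vdW radius (pair minimum at r_i + r_j); eps: LJ well depth
# gfree: desolvation free energy density (positive = penalty when buried,
#        negative = hydrophobic burial bonus); vol: occlusion volume
C_ali    2.00  0.12   0.00  -0.32  23.0  0  0
C_aro    1.95  0.12   0.00  -0.25  18.0  0  0
C_pol    1.90  0.10   0.00   0.00  10.0  0  0
N_bb     1.75  0.16   0.00   0.60   5.0  1  0
N_don    1.75  0.16   0.00   0.70  11.0  1  0
N_arom   1.70  0.16   0.00   0.60  11.0  0  1
N_pos    1.70  0.16   0.50   3.00  11.0  1  0
N_lys    1.70  0.16   1.00   4.00  11.0  1  0
O_bb     1.55  0.20   0.00   0.80  10.0  0  1
O_carb   1.55  0.20   0.00   0.85  10.0  0  1
O_coo    1.50  0.20  -0.50   2.00  10.0  0  1
O_oh     1.55  0.20   0.00   0.55  10.0  1  1
S_thi    1.90  0.45   0.00  -0.10  14.5  0  0
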