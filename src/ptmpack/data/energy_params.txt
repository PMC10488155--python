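# Heavy-atom pair-potential parameters for the flat-top Lennard-Jones clash
# score, keyed by element.  well_depth (kcal/mol) follows CHARMM param19
# heavy-atom classes; radius (Angstrom) is the hard-sphere contact radius,
# combined as sigma_ij = r_i + r_j and E_ij = sqrt(E_i * E_j).
# element  well_depth  radius
C  0.1200  1.75
N  0.2384  1.55
O  0.1591  1.45
S  0.0430  1.85
P  0.5850  1.85
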