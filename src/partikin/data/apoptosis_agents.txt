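# Apoptosis execution network, post-MOMP initial state.
# 14 species: apoptosome (Apop), pro/active/cleaved caspase-9 (PC9, C9, C9P),
# pro/active caspase-3 (PC3, C3), XIAP and its caspase complexes, SMAC and
# its XIAP complex, and the C3 FRET-substrate proxy.
# All cytosolic (soluble); concentrations referenced to the fixed box volume.
# Rate constants and concentrations are representative literature-scale
# values standing in for the original deposited parameter tables; edit this
# file to substitute measured values.
# columns: name localisation D[m2/s] c0[M] composition
name localisation D c0 composition
Apop      soluble 5.0e-12 1.0e-7 apop:1
PC9       soluble 3.0e-11 2.0e-8 c9:1
ApopPC9   soluble 5.0e-12 0.0    apop:1,c9:1
C9        soluble 3.0e-11 0.0    c9:1
C9P       soluble 3.0e-11 0.0    c9:1
PC3       soluble 3.0e-11 2.0e-7 c3:1
C3        soluble 3.0e-11 0.0    c3:1
XIAP      soluble 2.5e-11 3.0e-7 xiap:1
XIAPC3    soluble 2.0e-11 0.0    xiap:1,c3:1
XIAPC9    soluble 2.0e-11 0.0    xiap:1,c9:1
SMAC      soluble 3.5e-11 4.0e-7 smac:1
SMACXIAP  soluble 2.0e-11 0.0    smac:1,xiap:1
Substrate soluble 3.0e-11 5.0e-7 sub:1
CleavedSubstrate soluble 3.0e-11 0.0 sub:1
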