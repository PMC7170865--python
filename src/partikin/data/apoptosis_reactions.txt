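# Apoptosis execution network: 23 reactions.
# Topology: apoptosome binds and activates PC9; C9 (and the C3-cleaved C9P,
# which XIAP cannot inhibit) convert PC3 to C3; C3 cleaves C9 to C9P
# (positive feedback) and cleaves the substrate; XIAP reversibly binds C3
# and C9 and degrades the bound caspase; SMAC binds XIAP and breaks up
# caspase-XIAP complexes; slow basal turnover of the signalling proteins.
# columns: reaction type k_f[s-1 | M-1.s-1] k_r[s-1]
reaction type k_f k_r
Apop + PC9 <-> ApopPC9            reversible    1.0e6  1.0e-3
ApopPC9 -> Apop + C9              first_order   1.0e-1
C9 + PC3 -> C9 + C3               second_order  1.0e6
C9P + PC3 -> C9P + C3             second_order  3.0e6
C3 + C9 -> C3 + C9P               second_order  1.0e6
XIAP + C3 <-> XIAPC3              reversible    3.0e6  1.0e-3
XIAPC3 -> XIAP                    first_order   1.0e-3
XIAP + C9 <-> XIAPC9              reversible    1.0e6  1.0e-3
XIAPC9 -> XIAP                    first_order   1.0e-3
SMAC + XIAP <-> SMACXIAP          reversible    7.0e6  2.0e-3
SMAC + XIAPC3 -> SMACXIAP + C3    second_order  7.0e6
SMAC + XIAPC9 -> SMACXIAP + C9    second_order  7.0e6
C3 + Substrate -> C3 + CleavedSubstrate second_order 2.0e5
PC9 -> 0                          first_order   5.7e-5
PC3 -> 0                          first_order   5.7e-5
C9 -> 0                           first_order   5.7e-5
C9P -> 0                          first_order   5.7e-5
C3 -> 0                           first_order   5.7e-5
XIAP -> 0                         first_order   5.7e-5
XIAPC3 -> 0                       first_order   5.7e-5
XIAPC9 -> 0                       first_order   5.7e-5
SMAC -> 0                         first_order   5.7e-5
SMACXIAP -> 0                     first_order   5.7e-5
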