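# SYNTHETIC 4-gene demonstration network.
# Constructed so that its attractor set is exactly the five fixed points
# 0000, 1011, 0011, 1111, 1101 (basins 4, 4, 3, 3, 2 of 16; transient
# time 2), mirroring the attractor labels of the published 4-agent test
# case whose original supplementary rules are not redistributed here.
targets, factors
g1, g1 | (g2 & !g3 & !g4)
g2, (g1 & g2) | (g2 & !g4)
g3, (g1 & g3) | (g2 & g3) | (g3 & g4) | (g1 & g2 & !g4) | (g1 & g4 & !g2)
g4, (g2 & g3) | (g2 & g4) | (g3 & g4) | (g1 & !g2) | (g2 & !g1)
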