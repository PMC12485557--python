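# 5-gene Boolean model of mammalian cortical area development
# (Giacomantonio & Goodhill 2010, consensus network: Fgf8/Sp8 mutual
# activation, Emx2/Fgf8 and Emx2/Pax6 mutual repression, Coup_tfi
# repressed by the anterior factors).
# Two fixed-point attractors: the posterior expression pattern 01010
# (Emx2, Coup_tfi on; basin 28 of 32) and the anterior pattern 10101
# (Fgf8, Pax6, Sp8 on; basin 4 of 32).
targets, factors
Fgf8, Fgf8 & Sp8 & !Emx2
Emx2, Coup_tfi & !Fgf8 & !Pax6 & !Sp8
Pax6, Sp8 & !Emx2 & !Coup_tfi
Coup_tfi, !Fgf8 & !Sp8
Sp8, Fgf8 & !Emx2
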