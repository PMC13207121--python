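# Three-generation hEDS family: founders G1-Fa (affected) and G1-Mo
# (unaffected spouse); affected daughters G2-Da1 and G2-Da2; G2-So is the
# unaffected married-in spouse of G2-Da1; G3-Da is their affected child.
FAM1	G1-Fa	0	0	1	2
FAM1	G1-Mo	0	0	2	1
FAM1	G2-So	0	0	1	1
FAM1	G2-Da1	G1-Fa	G1-Mo	2	2
FAM1	G2-Da2	G1-Fa	G1-Mo	2	2
FAM1	G3-Da	G2-So	G2-Da1	2	2
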