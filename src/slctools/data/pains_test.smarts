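# Small PAINS test pattern set covering common alert classes.
# Format: pattern_id<TAB>SMARTS
# The full, versioned PAINS catalog is supplied by the user as an external
# file in the same format.
ene_rhod_A	O=C1CSC(=S)N1
catechol_A	c1ccc(O)c(O)c1
quinone_A	O=C1C=CC(=O)C=C1
azo_A	c1ccccc1N=Nc1ccccc1
hzone_phenol_A	c1cc(O)ccc1C=NN
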