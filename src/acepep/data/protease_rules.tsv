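# Default protease specificity rules: cleave the bond C-terminal to any P1
# residue unless the P1' residue is in the exclusion set.  These are
# simplified approximations of published specificities (papain's P2
# hydrophobic preference is collapsed to a broad P1 set; the three
# broad-spectrum microbial/plant enzymes get hydrophobic/aromatic P1 sets).
# Users with exact cleavage tables can substitute their own file.
# columns: enzyme<TAB>p1_set<TAB>p1prime_exclusions ("-" = none)
enzyme	p1_set	p1prime_exclusions
trypsin	KR	P
chymotrypsin A	FYW	P
pepsin pH1.3	FL	-
papain	RKFYWLVIAG	P
stem bromelain	AGVLIFYWKR	-
subtilisin	FYWLIVAM	-
proteinase K	AFYWLIV	-
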