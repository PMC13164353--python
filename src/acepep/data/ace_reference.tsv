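# Curated demonstration stand-in for a bioactive-peptide reference database.
# ACE-inhibitory entries are well-known food-derived di/tripeptides from the
# published literature (milk, fish, soy, egg, royal jelly hydrolysates);
# the short second activity set exercises multi-activity aggregation.
# This is NOT a redistribution of any database and is not exhaustive.
# columns: activity<TAB>sequence
activity	sequence
ACE inhibitor	IY
ACE inhibitor	VY
ACE inhibitor	KF
ACE inhibitor	IW
ACE inhibitor	LW
ACE inhibitor	VW
ACE inhibitor	AW
ACE inhibitor	FY
ACE inhibitor	GY
ACE inhibitor	RY
ACE inhibitor	YP
ACE inhibitor	AY
ACE inhibitor	KW
ACE inhibitor	LF
ACE inhibitor	AF
ACE inhibitor	GF
ACE inhibitor	RF
ACE inhibitor	TF
ACE inhibitor	LY
ACE inhibitor	IF
ACE inhibitor	VF
ACE inhibitor	HL
ACE inhibitor	AP
ACE inhibitor	KP
ACE inhibitor	GP
ACE inhibitor	RP
ACE inhibitor	IPP
ACE inhibitor	VPP
ACE inhibitor	LKP
ACE inhibitor	IKP
ACE inhibitor	FQP
ACE inhibitor	IKW
ACE inhibitor	LRP
ACE inhibitor	IVY
ACE inhibitor	LQP
DPP IV inhibitor	GP
DPP IV inhibitor	PG
DPP IV inhibitor	VA
DPP IV inhibitor	GA
DPP IV inhibitor	PP
DPP IV inhibitor	IPI
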