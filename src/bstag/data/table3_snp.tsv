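marker	accession	snp	role	allele	tag	dye	sequence
LLL0729	DC891931	C/G	LSO				gtttcttGAAGTAGAAGGATGATAATCAC
LLL0729	DC891931	C/G	ASO	C	F9GAC	NED	CTAGTATCAGGACGACATGGACACAACTCAAGTtC
LLL0729	DC891931	C/G	ASO	G	F9GTC	PET	CTAGTATGAGGACGTCAATGGACACAACTCAAGTtG
MAPGR75R	DC893380	A/T	LSO				gtttcttGGTTGGTATATCTACGAGAC
MAPGR75R	DC893380	A/T	ASO	T	F9GTC	PET	CTAGTATGAGGACGTCTATCCGATTGAGCCTTTcT
MAPGR75R	DC893380	A/T	ASO	A	F9TAC	6-FAM	CTAGTATCAGGACTACATCCGATTGAGCCTTTcA
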