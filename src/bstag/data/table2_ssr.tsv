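marker	accession	motif	role	tag	dye	size_min	size_max	sequence
SSR08A04	DY293653	(aaac)n	forward	F9GCC	VIC	180	220	CTAGTATTAGGACGCCCAAACACTTATTCGGGATCAG
SSR08A04	DY293653	(aaac)n	reverse					gtttcttAATGCCATTATCAAACCGCC
SSR08A09	CX663959	(cagg)n	forward	F9GTC	PET	150	190	CTAGTATGAGGACGTCCATCATTGCATCAGCATCAC
SSR08A09	CX663959	(cagg)n	reverse					gtttcttAGTTCTACATCATAACCTGCC
SSR08B15	DY292389	(acc)n	forward	F9GAC	NED	210	250	CTAGTATCAGGACGACCCCATACTTGAAACCAAACC
SSR08B15	DY292389	(acc)n	reverse					gtttcttAGCAGCATGACTTAATCCA
SSR08B25	DY289996	(tta)n	forward	F9TAC	6-FAM	120	160	CTAGTATCAGGACTACCGTTGACTCTCAAGAGATCTG
SSR08B25	DY289996	(tta)n	reverse					gtttcttCTTCACAGTCCGCAGCATTA
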