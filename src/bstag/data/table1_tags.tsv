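name	sequence	tm
F9GAC	CTAGTATCAGGACGAC	51.3
F9GTC	CTAGTATGAGGACGTC	51.3
F9TAC	CTAGTATCAGGACTAC	47.2
F9GCC	CTAGTATTAGGACGCC	51.7
F9CCG	CTAGTATTAGGACCCG	50.8
F9AGG	CTAGTATTAGGACAGG	47.5
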