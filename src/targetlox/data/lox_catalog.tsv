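name	left_arm	linker	right_arm	linker_class	left_arm_state	right_arm_state
loxP	ATAACTTCGTATA	ATGTATGC	TATACGAAGTTAT	P	wild_type	wild_type
lox66	ATAACTTCGTATA	ATGTATGC	TATACGAACGGTA	P	wild_type	mutant
lox71	TACCGTTCGTATA	ATGTATGC	TATACGAAGTTAT	P	mutant	wild_type
lox72	TACCGTTCGTATA	ATGTATGC	TATACGAACGGTA	P	mutant	mutant
lox511	ATAACTTCGTATA	ATGTATAC	TATACGAAGTTAT	511	wild_type	wild_type
loxFAS	ATAACTTCGTATA	TACCTTTC	TATACGAAGTTAT	FAS	wild_type	wild_type
loxm2	ATAACTTCGTATA	AGAAACCA	TATACGAAGTTAT	m2	wild_type	wild_type
lox2272	ATAACTTCGTATA	AAGTATCC	TATACGAAGTTAT	2272	wild_type	wild_type
loxN	ATAACTTCGTATA	GTATACCT	TATACGAAGTTAT	N	wild_type	wild_type
lox511/71	TACCGTTCGTATA	ATGTATAC	TATACGAAGTTAT	511	mutant	wild_type
lox511/66	ATAACTTCGTATA	ATGTATAC	TATACGAACGGTA	511	wild_type	mutant
loxFAS/71	TACCGTTCGTATA	TACCTTTC	TATACGAAGTTAT	FAS	mutant	wild_type
loxFAS/66	ATAACTTCGTATA	TACCTTTC	TATACGAACGGTA	FAS	wild_type	mutant
loxm2/71	TACCGTTCGTATA	AGAAACCA	TATACGAAGTTAT	m2	mutant	wild_type
loxm2/66	ATAACTTCGTATA	AGAAACCA	TATACGAACGGTA	m2	wild_type	mutant
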