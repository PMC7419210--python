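lineage	library	coverage_lo	coverage_hi	n_clones	copy_number	previously_reported
Gray mouse lemur	CHORI-257	7.7	7.7	4	1
Dusky titi	LBNL-5	9.4	9.4	12	<2
Owl monkey	CHORI-258	5	5	15	<2
Squirrel monkey	CHORI-254	.	.	40	6
Marmoset	CHORI-259	.	.	110	18
Macaque	CHORI-250	5.5	6	14	1	*
Baboon	RPCI-41	5.2	5.2	9	1	*
Orangutan	CHORI-253	5	6	127	20	*
Gorilla	CHORI-255	6	7	113	16	*
Chimpanzee	RPCI4-43/CHOR-251	5	6	212	37	*
Human	RPCI-11	5	7	.	17	*
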