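2	0	93300000	2p
4	0	50400000	4p
6	61000000	171115067	6q
11	53700000	135006516	11q
13	17900000	115169878	13q
14	17600000	107349540	14q
17	0	22200000	17p
17	7565097	7590856	TP53
11	108093211	108239829	ATM
11	102188181	102210135	BIRC3
13	48877883	49056122	RB1
13	50000000	50700000	13q14_MDR
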