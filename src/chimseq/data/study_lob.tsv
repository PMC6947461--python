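label	chrom	pos	ref	mut	depth_mean	depth_sd	pct_be	pct_sd
NRAS:c.35G>A	chr1	115258747	G	A	2048.7	416.2	0.026	0.041
SF3B1:c.2098A>G	chr2	198266834	A	G	1930.5	365.2	0.018	0.031
SETBP1:c.2608G>A	chr18	42531913	G	A	1598.5	313.4	0.041	0.064
U2AF1:c.101C>T	chr21	44524456	C	T	1410.7	351.4	0.026	0.055
U2AF1:c.101C>A	chr21	44524456	C	A	1410.7	351.4	0.026	0.055
PHF6:c.820C>T	chrX	133549136	C	T	1184.0	455.8	0.023	0.052
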