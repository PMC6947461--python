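sample	patient	group	stage	label	mab
p01_pre	1	complete	pre	U2AF1:c.101C>T	22.40
p01_pre	1	complete	pre	SETBP1:c.2608G>A	6.60
p01_post1	1	complete	post	U2AF1:c.101C>T	0.00
p01_post1	1	complete	post	SETBP1:c.2608G>A	0.00
p02_pre	2	complete	pre	SF3B1:c.2098A>G	10.33
p02_post1	2	complete	post	SF3B1:c.2098A>G	0.00
p03_pre	3	complete	pre	U2AF1:c.101C>T	31.78
p03_post1	3	complete	post	U2AF1:c.101C>T	0.00
p04_pre	4	complete	pre	U2AF1:c.101C>A	37.64
p04_post1	4	complete	post	U2AF1:c.101C>A	0.15
p05_pre	5	complete	pre	U2AF1:c.101C>T	26.22
p05_post1	5	complete	post	U2AF1:c.101C>T	0.00
p06_pre	6	complete	pre	U2AF1:c.101C>A	6.88
p06_post1	6	complete	post	U2AF1:c.101C>A	0.10
p07_pre	7	complete	pre	U2AF1:c.101C>T	46.74
p07_pre	7	complete	pre	NRAS:c.35G>A	3.69
p07_post1	7	complete	post	U2AF1:c.101C>T	0.00
p07_post1	7	complete	post	NRAS:c.35G>A	0.00
p08_pre	8	complete	pre	U2AF1:c.101C>A	7.10
p08_post1	8	complete	post	U2AF1:c.101C>A	0.08
p11_pre	11	mixed	pre	U2AF1:c.101C>T	29.59
p11_post1	11	mixed	post	U2AF1:c.101C>T	0.10
p11_post2	11	mixed	post	U2AF1:c.101C>T	0.09
p11_post3	11	mixed	post	U2AF1:c.101C>T	10.89
p11_post4	11	mixed	post	U2AF1:c.101C>T	0.17
p11_post5	11	mixed	post	U2AF1:c.101C>T	0.00
p11_post6	11	mixed	post	U2AF1:c.101C>T	0.18
p11_post7	11	mixed	post	U2AF1:c.101C>T	1.08
p12_pre	12	mixed	pre	SF3B1:c.2098A>G	17.13
p12_post1	12	mixed	post	SF3B1:c.2098A>G	0.08
p12_post2	12	mixed	post	SF3B1:c.2098A>G	0.61
p12_post3	12	mixed	post	SF3B1:c.2098A>G	0.44
p13_pre	13	mixed	pre	NRAS:c.35G>A	16.91
p13_post1	13	mixed	post	NRAS:c.35G>A	0.00
p13_post2	13	mixed	post	NRAS:c.35G>A	0.00
p13_post3	13	mixed	post	NRAS:c.35G>A	0.00
p14_pre	14	dcl	pre	PHF6:c.820C>T	0.00
p14_post1	14	dcl	post	PHF6:c.820C>T	9.21
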