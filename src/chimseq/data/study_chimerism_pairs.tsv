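sample	patient	group	ref_pct	test_pct
p01_post1	1	complete	99.4	99.94
p02_post1	2	complete	100	99.87
p03_post1	3	complete	99.1	99.97
p04_post1	4	complete	99.9	99.91
p05_post1	5	complete	100	99.93
p06_post1	6	complete	97.8	98.28
p07_post1	7	complete	98.2	98.81
p08_post1	8	complete	99.6	99.87
p09_post1	9	complete	99.7	99.86
p10_post1	10	mixed	76.9	80.56
p10_post2	10	mixed	69.7	72.00
p11_post1	11	mixed	99.9	99.88
p11_post2	11	mixed	99.4	99.39
p11_post3	11	mixed	74.0	72.49
p11_post4	11	mixed	99.0	99.85
p11_post5	11	mixed	98.0	99.23
p11_post6	11	mixed	100	99.09
p11_post7	11	mixed	95.0	95.23
p12_post1	12	mixed	90.9	92.91
p12_post2	12	mixed	91.7	92.84
p12_post3	12	mixed	90.2	92.35
p13_post1	13	mixed	83.7	85.44
p13_post2	13	mixed	92.7	94.37
p13_post3	13	mixed	60.9	NA
p14_post1	14	dcl	100	99.80
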