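outcome	vaccine_group	G1	G1+G3	G1+G2	G1+G2_LTR	G1+G2+G2_LTR
protected	O	4	4	1	0	0
protected	S	2	4	1	0	0
protected	X	4	1	1	0	0
not_protected	O	2	1	0	2	1
not_protected	S	3	2	0	2	0
not_protected	X	3	4	1	1	0
not_protected	E	6	4	1	1	0
exposed_uninfected	E	3	0	0	0	0
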