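sample	A	B	C	D	E	F	G
SZ1	1	0	1	0	0	0	0
SZ2	0	1	1	0	0	0	0
SZ3	1	1	1	0	0	0	0
SZ4	0	1	1	0	0	0	0
SZ5	0	1	0	0	0	0	0
SZ6	0	0	1	0	0	0	0
SZ7	1	1	1	0	0	0	1
SZ8	0	0	0	0	0	0	0
BD1	0	0	1	1	1	0	0
BD2	0	1	1	1	0	0	0
BD3	0	1	1	0	0	1	0
BD4	0	1	1	0	0	1	0
BD5	0	0	0	1	0	0	0
BD6	0	1	0	1	0	0	0
BD7	0	0	0	0	1	0	0
BD8	0	0	0	0	1	0	0
BD9	0	0	0	0	1	0	0
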