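ZA253	III-8	0	0	1	2	1
ZA253	III-7	0	0	1	2	1
ZA253	IV-2	0	0	1	2	1
ZA253	III-6	0	0	2	2	0
ZA253	III-2	0	0	2	2	0
ZA253	III-4	0	0	0	1	0
ZA253	IV-1	0	0	0	1	0
ZA253	III-1	0	0	0	1	0
ZA253	III-5	0	0	0	1	0
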