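gene	cdna	protein	chrom	pos	ref	alt	consequence	zygosity	sift	polyphen2	mutationtaster	gerp	cadd	condel	ac	an	source
CFAP65	c.A3151G	p.T1023A	2	219886565	T	C	missense	het	0.0	0.124	1.0	2.38	18.7	0.763	25	281690	gnomAD_r2_1
RFT1	c.C1450G	p.A463G	3	53122500	C	G	missense	het	0.49	0.001	0.0	2.53	4.96	0.042	.	.	.
NRXN2	c.G3008A	p.G849D	11	64420000	G	A	missense	het	0.0	0.973	1.0	4.93	29.5	0.831	.	.	.
TEP1	c.A1276G	p.Y412C	14	20850000	A	G	missense	het	0.51	0.0	0.0	-8.29	0.0	0.05	.	.	.
CCNF	c.G1176C	p.C363S	16	2480000	G	C	missense	het	0.06	0.939	1.0	5.43	27.3	0.707	.	.	.
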